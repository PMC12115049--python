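"""APCS-MLR receptor model (Thurston-style source apportionment).

The model works backwards from concentrations measured at receptors to
source contributions, without emission inventories:

1. standardize each metal column to zero mean, unit variance;
2. PCA on the metal correlation matrix, retaining components with
   eigenvalue > 1 (Kaiser criterion);
3. rescale component scores to *absolute* principal component scores
   (APCS) by subtracting the score of an artificial sample whose
   concentrations are all zero — this anchors scores at a true
   zero-concentration origin so they read as source intensities;
4. per metal, ordinary least squares of concentration on the APCS
   columns; slope x mean APCS gives each component's mean contribution
   and the intercept an "unidentified" contribution;
5. contributions are normalized (on absolute values, guarding against
   sign indeterminacy) into percent shares summing to 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_core import ConcentrationTable

logger = logging.getLogger("metalsource")

UNIDENTIFIED = "unidentified"


def standardize(conc: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Standardize each metal column: Z = (C - mean) / sd (sample sd).

    Raises on a zero-variance metal, naming it.
    """
    mean = conc.mean()
    sd = conc.std(ddof=1)
    dead = sd.index[sd <= 0].tolist()
    if dead:
        raise ValueError(f"zero-variance metal column(s): {', '.join(map(str, dead))}")
    return (conc - mean) / sd, mean, sd


def fit_pca(z: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, int]:
    """Eigendecomposition of the metal correlation matrix.

    Returns ``(loadings, eigenvalues, q)``: loadings are eigenvectors
    scaled by sqrt(eigenvalue) (so loadings @ loadings.T reproduces the
    correlation matrix), components are ordered by descending
    eigenvalue and sign-flipped so each component's largest-magnitude
    loading is positive, and q counts eigenvalues > 1 (Kaiser).
    """
    if z.shape[1] < 2 or z.shape[0] < 3:
        raise ValueError("PCA needs at least 2 metals and 3 samples")
    corr = np.corrcoef(z.to_numpy(dtype=float), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if np.any(eigval < -1e-8):
        logger.warning("correlation matrix numerically indefinite; clipping")
    tiny = eigval < 1e-12
    if tiny.any():
        logger.warning("correlation matrix rank-deficient (%d null dimension(s))", tiny.sum())
    eigval = np.clip(eigval, 0.0, None)
    # sign convention: largest-|loading| entry positive
    for j in range(eigvec.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] *= -1
    loadings = eigvec * np.sqrt(eigval)
    q = int((eigval > 1.0).sum())
    names = [f"PC{j + 1}" for j in range(len(eigval))]
    return pd.DataFrame(loadings, index=z.columns, columns=names), eigval, q


@dataclass
class ApcsModel:
    """Fitted APCS-MLR model for one concentration table."""

    metals: tuple[str, ...]
    mean: pd.Series
    sd: pd.Series
    loadings: pd.DataFrame          # metal x all components
    eigenvalues: np.ndarray
    q: int                          # Kaiser-retained component count
    score_coef: pd.DataFrame        # metal x retained components
    az: pd.DataFrame                # standardized scores, sample x retained
    a0: pd.Series                   # zero-sample scores per retained component
    apcs: pd.DataFrame              # absolute scores, sample x retained
    regression: pd.DataFrame        # per metal: intercept, b_PCj..., r2
    contributions: pd.DataFrame     # metal x (PCj..., unidentified), percent

    @property
    def components(self) -> list[str]:
        return list(self.apcs.columns)

    @property
    def explained_variance_pct(self) -> pd.Series:
        pct = 100.0 * self.eigenvalues / len(self.metals)
        return pd.Series(pct, index=self.loadings.columns)


def score_coefficients(loadings: pd.DataFrame, eigenvalues: np.ndarray, q: int) -> pd.DataFrame:
    """Score-coefficient matrix S for the q retained components.

    With loadings L_j = v_j*sqrt(l_j), S_j = v_j/sqrt(l_j) = L_j/l_j,
    so that Z @ S yields unit-variance component scores.
    """
    if q < 1:
        raise ValueError("no component retained (all eigenvalues <= 1)")
    cols = loadings.columns[:q]
    return loadings[cols] / eigenvalues[:q]


def absolute_scores(
    conc: pd.DataFrame, mean: pd.Series, sd: pd.Series, score_coef: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Compute standardized scores AZ, zero-sample scores A0, and
    absolute scores APCS = AZ - A0.

    A0 is the score of an artificial sample with all concentrations
    zero, i.e. standardized values Z0 = (0 - mean)/sd, so the APCS of a
    true all-zero sample is exactly the zero vector.
    """
    z = (conc - mean) / sd
    az = z @ score_coef
    z0 = -mean / sd
    a0 = z0 @ score_coef
    apcs = az - a0
    return az, a0, apcs


def fit_source_regression(
    apcs: pd.DataFrame, conc: pd.DataFrame, max_condition: float = 1e8
) -> pd.DataFrame:
    """OLS per metal: C_metal ~ b0 + sum_j b_j * APCS_j.

    Returns a frame indexed by metal with the intercept, one slope per
    component, and the fit R^2. Raises if the APCS design is
    (near-)collinear or if n <= q + 1.
    """
    n, q = apcs.shape
    if n <= q + 1:
        raise ValueError(f"need more samples ({n}) than components + 1 ({q + 1})")
    x = sm.add_constant(apcs.to_numpy(dtype=float))
    cond = np.linalg.cond(x)
    if cond > max_condition:
        raise ValueError(f"APCS columns are collinear (condition number {cond:.3g})")
    rows = []
    for metal in conc.columns:
        fit = sm.OLS(conc[metal].to_numpy(dtype=float), x).fit()
        row = {"metal": metal, "intercept": fit.params[0], "r2": fit.rsquared}
        for j, comp in enumerate(apcs.columns):
            row[f"b_{comp}"] = fit.params[j + 1]
        rows.append(row)
    return pd.DataFrame(rows).set_index("metal")


def source_contributions(regression: pd.DataFrame, apcs: pd.DataFrame) -> pd.DataFrame:
    """Percent contribution of each component (plus an unidentified
    term) to each metal's mean concentration.

    The mean contribution of component j to metal i is
    b_ij * mean(APCS_j); the unidentified contribution is the
    intercept. Shares are |contribution| / sum(|contributions|) * 100.
    """
    mean_scores = apcs.mean(axis=0)
    comps = list(apcs.columns)
    rows = []
    for metal, reg in regression.iterrows():
        contrib = {c: reg[f"b_{c}"] * mean_scores[c] for c in comps}
        contrib[UNIDENTIFIED] = reg["intercept"]
        total = sum(abs(v) for v in contrib.values())
        if total == 0:
            raise ValueError(f"all-zero predicted mean for metal {metal!r}")
        rows.append({"metal": metal, **{k: 100.0 * abs(v) / total for k, v in contrib.items()}})
    return pd.DataFrame(rows).set_index("metal")


def fit_apcs_mlr(table: ConcentrationTable) -> ApcsModel:
    """Run the full APCS-MLR pipeline on one concentration table."""
    conc = table.concentrations()
    z, mean, sd = standardize(conc)
    loadings, eigval, q = fit_pca(z)
    coef = score_coefficients(loadings, eigval, q)
    az, a0, apcs = absolute_scores(conc, mean, sd, coef)
    regression = fit_source_regression(apcs, conc)
    contributions = source_contributions(regression, apcs)
    return ApcsModel(
        metals=tuple(conc.columns), mean=mean, sd=sd, loadings=loadings,
        eigenvalues=eigval, q=q, score_coef=coef, az=az, a0=a0, apcs=apcs,
        regression=regression, contributions=contributions,
    )


def dominant_component(model: ApcsModel, metal: str) -> str:
    """The retained component with the largest share for a metal
    (the unidentified term excluded)."""
    shares = model.contributions.loc[metal, model.components]
    return str(shares.idxmax())
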