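"""Covariate-adjusted association of outcome domains with cerebellar features.

Each (feature, domain) pair is tested with an ordinary least-squares model

    score ~ feature + sex + pma_weeks + birthweight_g

reporting the feature coefficient's t statistic and two-sided p-value on
n - 5 degrees of freedom (intercept + feature + 3 covariates), followed by
Benjamini-Hochberg FDR adjustment.  The default FDR scope is per outcome
domain across features (10 tests for a 10-gradient table, 8 for a
volume table).  Complete cases only: subjects missing any model column
are dropped per model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEFAULT_COVARIATES",
    "AssociationResult",
    "fit_feature_model",
    "bh_fdr",
    "association_table",
    "volume_growth",
    "domain_intercorrelation",
]

DEFAULT_COVARIATES = ("sex", "pma_weeks", "birthweight_g")


@dataclass
class AssociationResult:
    feature: str
    outcome: str
    t_stat: float
    p_unc: float
    n: int
    p_fdr: float | None = None


def fit_feature_model(
    data: pd.DataFrame,
    outcome: str,
    feature: str,
    covariates: tuple = DEFAULT_COVARIATES,
) -> AssociationResult:
    """OLS association of one feature with one outcome, covariate-adjusted."""
    cols = [outcome, feature, *covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    sub = data[cols].dropna()
    n = len(sub)
    n_params = 2 + len(covariates)  # intercept + feature + covariates
    if n <= n_params:
        raise ValueError(f"n={n} too small for {n_params} parameters")
    X = sm.add_constant(sub[[feature, *covariates]].to_numpy(float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(sub[outcome].to_numpy(float), X).fit()
    return AssociationResult(
        feature=feature,
        outcome=outcome,
        t_stat=float(fit.tvalues[1]),
        p_unc=float(fit.pvalues[1]),
        n=n,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``adj_(i) = min_{j >= i} p_(j) * m / j`` over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def association_table(
    data: pd.DataFrame,
    features: list[str],
    domains: list[str],
    fdr_scope: str = "per_domain",
    covariates: tuple = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """One OLS model per (feature, domain) with BH-FDR adjustment.

    ``fdr_scope`` is ``"per_domain"`` (BH across features within each
    domain, the default) or ``"global"`` (one BH family over all cells).
    Returns a long-form frame: feature, outcome, t_stat, p_unc, p_fdr, n.
    """
    if fdr_scope not in ("per_domain", "global"):
        raise ValueError("fdr_scope must be 'per_domain' or 'global'")
    results = [
        fit_feature_model(data, outcome=dom, feature=feat, covariates=covariates)
        for dom in domains
        for feat in features
    ]
    table = pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "outcome": [r.outcome for r in results],
            "t_stat": [r.t_stat for r in results],
            "p_unc": [r.p_unc for r in results],
            "n": [r.n for r in results],
        }
    )
    if fdr_scope == "global":
        table["p_fdr"] = bh_fdr(table["p_unc"].to_numpy())
    else:
        table["p_fdr"] = np.nan
        for dom in domains:
            sel = table["outcome"] == dom
            table.loc[sel, "p_fdr"] = bh_fdr(table.loc[sel, "p_unc"].to_numpy())
    return table


def volume_growth(volumes: pd.DataFrame, pma: np.ndarray) -> pd.DataFrame:
    """Per-ROI Pearson correlation of volume with PMA.

    Returns one row per ROI with r, percent variance explained (100 r^2),
    p, and BH-adjusted p across the ROIs.
    """
    pma = np.asarray(pma, dtype=float)
    roi_cols = [c for c in volumes.columns if c != "subject_id"]
    if len(pma) != len(volumes):
        raise ValueError("PMA length does not match volume table")
    if len(pma) < 3:
        raise ValueError("need at least 3 subjects")
    rows = []
    for roi in roi_cols:
        vals = volumes[roi].to_numpy(float)
        if vals.std() == 0:
            raise ValueError(f"zero-variance volume column: {roi}")
        r, p = sps.pearsonr(vals, pma)
        rows.append({"roi": roi, "r": r, "pct_variance": 100.0 * r**2, "p_unc": p})
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p_unc"].to_numpy())
    return out


def domain_intercorrelation(scores: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations between outcome domains.

    Returns (r matrix, p matrix), both symmetric with unit/zero diagonal.
    """
    cols = list(scores.columns)
    if len(scores) < 3:
        raise ValueError("need at least 3 subjects")
    for c in cols:
        if scores[c].std() == 0:
            raise ValueError(f"constant domain column: {c}")
    k = len(cols)
    rmat = np.eye(k)
    pmat = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            pair = scores[[cols[a], cols[b]]].dropna()
            r, p = sps.pearsonr(pair[cols[a]], pair[cols[b]])
            rmat[a, b] = rmat[b, a] = r
            pmat[a, b] = pmat[b, a] = p
    return (
        pd.DataFrame(rmat, index=cols, columns=cols),
        pd.DataFrame(pmat, index=cols, columns=cols),
    )
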