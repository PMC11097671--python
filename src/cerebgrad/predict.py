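"""Leakage-safe cross-validated prediction of outcome scores with a permutation null.

Scores on each outcome domain are predicted from cerebellar features with a
10-fold cross-validated ordinary-least-squares model.  Three feature sets
are supported:

* ``functional`` — gradient coefficients, with the group PCA re-fitted on
  the training subjects of every fold and held-out subjects projected with
  the training means (no information from test subjects reaches the basis);
* ``anatomical`` — the 8 ROI volumes;
* ``combined`` — both blocks concatenated, each column standardized on
  training statistics.

Non-imaging covariates are deliberately excluded from the predictor set.
Performance per repeat is the Pearson correlation between pooled
out-of-fold predictions and actual scores, Fisher-z transformed; the
reported summary is mean z +/- its standard error over repeats.
Significance comes from a permutation test: scores are shuffled, one full
CV cycle is run per permutation, and the one-sided p-value uses the
add-one rule ``p = (1 + #{null >= observed}) / (1 + n_permutations)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import GroupMatrix
from .gradients import fit_group_pca, project_subjects

__all__ = [
    "PredictionConfig",
    "PredictionResult",
    "fisher_z",
    "cv_predict",
    "permutation_test",
    "run_prediction",
    "compare_feature_sets",
]

FEATURE_SETS = ("functional", "anatomical", "combined")


@dataclass
class PredictionConfig:
    n_folds: int = 10
    n_repeats: int = 100
    n_permutations: int = 5000
    feature_set: str = "functional"
    k_components: int = 10
    seed: int = 0
    observed_stat: str = "mean_z"  # or "single": first repeat's z

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
        if self.observed_stat not in ("mean_z", "single"):
            raise ValueError("observed_stat must be 'mean_z' or 'single'")


@dataclass
class PredictionResult:
    domain: str
    feature_set: str
    subject_ids: list[str]
    predictions: np.ndarray  # n_repeats x n_subjects, out-of-fold
    per_repeat_r: np.ndarray
    per_repeat_z: np.ndarray
    mean_z: float
    se_z: float
    permutation_null: np.ndarray | None = None
    p_perm: float | None = None


def fisher_z(r: float) -> float:
    """Variance-stabilizing transform z = atanh(r); requires |r| < 1."""
    r = float(r)
    if abs(r) >= 1:
        raise ValueError(
            f"|r|={abs(r)} >= 1: Fisher z is infinite. This arises with degenerate "
            "(e.g. noiseless, duplicated) data; perturb the inputs or drop the repeat."
        )
    return float(np.arctanh(r))


def _make_folds(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded shuffle, then contiguous blocks of near-equal size."""
    return [np.sort(f) for f in np.array_split(rng.permutation(n), n_folds)]


def _align_inputs(
    subjects: pd.DataFrame,
    group: GroupMatrix | None,
    volumes: pd.DataFrame | None,
    domain: str,
    feature_set: str,
):
    """Complete-case alignment of subjects, FC columns and volume rows."""
    if domain not in subjects.columns:
        raise ValueError(f"domain column '{domain}' not in subject table")
    need_fc = feature_set in ("functional", "combined")
    need_vol = feature_set in ("anatomical", "combined")
    if need_fc and group is None:
        raise ValueError(f"feature_set '{feature_set}' requires the group FC matrix")
    if need_vol and volumes is None:
        raise ValueError(f"feature_set '{feature_set}' requires the volume table")
    ids = subjects.loc[subjects[domain].notna(), "subject_id"].tolist()
    if need_fc:
        ids = [s for s in ids if s in set(group.subject_ids)]
    if need_vol:
        ids = [s for s in ids if s in set(volumes["subject_id"])]
    if len(ids) < 10:
        raise ValueError(f"only {len(ids)} complete-case subjects; too few for CV")
    y = (
        subjects.set_index("subject_id").loc[ids, domain].to_numpy(float)
    )
    fc = None
    if need_fc:
        col = {s: i for i, s in enumerate(group.subject_ids)}
        fc = group.subset([col[s] for s in ids])
    vol = None
    if need_vol:
        roi_cols = [c for c in volumes.columns if c != "subject_id"]
        vol = volumes.set_index("subject_id").loc[ids, roi_cols].to_numpy(float)
    return ids, y, fc, vol


def _fold_features(
    fc: GroupMatrix | None,
    vol: np.ndarray | None,
    train: np.ndarray,
    test: np.ndarray,
    feature_set: str,
    k: int,
):
    """Training/test design blocks for one fold, training-derived only."""
    blocks_train, blocks_test = [], []
    if feature_set in ("functional", "combined"):
        k_eff = min(k, len(train) - 1)
        model = fit_group_pca(fc.subset(train), k=k_eff)
        blocks_train.append(model.coefficients.T)
        blocks_test.append(project_subjects(model, fc.subset(test)).T)
    if feature_set in ("anatomical", "combined"):
        blocks_train.append(vol[train])
        blocks_test.append(vol[test])
    Xtr = np.hstack(blocks_train)
    Xte = np.hstack(blocks_test)
    if feature_set == "combined":
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("zero-variance feature column in training fold")
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd
    return Xtr, Xte


def _one_cv_cycle(
    y: np.ndarray,
    fc: GroupMatrix | None,
    vol: np.ndarray | None,
    config: PredictionConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, float]:
    """One random fold partition; returns (pooled predictions, r, z)."""
    n = y.size
    preds = np.empty(n)
    for test in _make_folds(n, config.n_folds, rng):
        train = np.setdiff1d(np.arange(n), test)
        Xtr, Xte = _fold_features(fc, vol, train, test, config.feature_set, config.k_components)
        if len(train) < Xtr.shape[1] + 2:
            raise ValueError(
                f"fold has {len(train)} training subjects for {Xtr.shape[1]} predictors"
            )
        A = np.column_stack([np.ones(len(train)), Xtr])
        beta, *_ = np.linalg.lstsq(A, y[train], rcond=None)
        preds[test] = np.column_stack([np.ones(len(test)), Xte]) @ beta
    r = float(np.corrcoef(preds, y)[0, 1])
    return preds, r, fisher_z(r)


def cv_predict(
    subjects: pd.DataFrame,
    group: GroupMatrix | None,
    volumes: pd.DataFrame | None,
    domain: str,
    config: PredictionConfig,
) -> PredictionResult:
    """Repeated 10-fold cross-validated prediction of one domain's scores.

    Each repeat re-partitions subjects into folds (seeded), refits features
    and the OLS model per fold on training data only, and pools out-of-fold
    predictions; every subject is predicted exactly once per repeat.
    """
    ids, y, fc, vol = _align_inputs(subjects, group, volumes, domain, config.feature_set)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 101)))
    n = y.size
    predictions = np.empty((config.n_repeats, n))
    rs = np.empty(config.n_repeats)
    zs = np.empty(config.n_repeats)
    for rep in range(config.n_repeats):
        predictions[rep], rs[rep], zs[rep] = _one_cv_cycle(y, fc, vol, config, rng)
    se = float(zs.std(ddof=1) / np.sqrt(len(zs))) if len(zs) > 1 else 0.0
    return PredictionResult(
        domain=domain,
        feature_set=config.feature_set,
        subject_ids=ids,
        predictions=predictions,
        per_repeat_r=rs,
        per_repeat_z=zs,
        mean_z=float(zs.mean()),
        se_z=se,
    )


def permutation_test(
    observed: float,
    subjects: pd.DataFrame,
    group: GroupMatrix | None,
    volumes: pd.DataFrame | None,
    domain: str,
    config: PredictionConfig,
) -> tuple[np.ndarray, float]:
    """Permutation null for the CV prediction performance.

    Each permutation shuffles the outcome scores once and runs a single
    full CV cycle with the same pipeline settings; the one-sided p-value
    (higher performance = more extreme) uses the add-one rule.
    """
    if config.n_permutations < 20:
        warnings.warn(
            f"n_permutations={config.n_permutations} is very small; "
            "p-value resolution will be poor",
            stacklevel=2,
        )
    _, y, fc, vol = _align_inputs(subjects, group, volumes, domain, config.feature_set)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 202)))
    null = np.empty(config.n_permutations)
    for i in range(config.n_permutations):
        y_perm = rng.permutation(y)
        _, _, null[i] = _one_cv_cycle(y_perm, fc, vol, config, rng)
    p = float((1 + np.sum(null >= observed)) / (1 + config.n_permutations))
    return null, p


def run_prediction(
    subjects: pd.DataFrame,
    group: GroupMatrix | None,
    volumes: pd.DataFrame | None,
    domain: str,
    config: PredictionConfig,
) -> PredictionResult:
    """cv_predict + permutation test in one call."""
    result = cv_predict(subjects, group, volumes, domain, config)
    observed = result.mean_z if config.observed_stat == "mean_z" else float(result.per_repeat_z[0])
    null, p = permutation_test(observed, subjects, group, volumes, domain, config)
    result.permutation_null = null
    result.p_perm = p
    return result


def compare_feature_sets(
    subjects: pd.DataFrame,
    group: GroupMatrix,
    volumes: pd.DataFrame,
    domains: list[str],
    config: PredictionConfig,
) -> pd.DataFrame:
    """Run every domain x {functional, anatomical, combined} cell.

    Returns a 4 x 3 (domains x feature sets) long-form grid of mean_z,
    se_z and permutation p, mirroring a prediction-performance figure.
    """
    rows = []
    for domain in domains:
        for feature_set in FEATURE_SETS:
            cfg = PredictionConfig(
                n_folds=config.n_folds,
                n_repeats=config.n_repeats,
                n_permutations=config.n_permutations,
                feature_set=feature_set,
                k_components=config.k_components,
                seed=config.seed,
                observed_stat=config.observed_stat,
            )
            res = run_prediction(subjects, group, volumes, domain, cfg)
            rows.append(
                {
                    "domain": domain,
                    "feature_set": feature_set,
                    "mean_z": res.mean_z,
                    "se_z": res.se_z,
                    "p_perm": res.p_perm,
                    "n": len(res.subject_ids),
                }
            )
    return pd.DataFrame(rows)
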