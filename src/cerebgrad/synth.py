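"""Synthetic neonatal cohort generator with known ground truth.

Emulates the data structure of a neonatal cerebellar rs-fMRI study after
preprocessing: per-subject voxels x time BOLD matrices whose covariance is
driven by a small number of latent connectivity sources, six-parameter
motion traces with occasional spikes, demographic covariates (sex,
postmenstrual age at scan, birthweight), PMA-dependent ROI volumes, and
four toddler social-emotional outcome domains on a t-score scale
(mean 50, SD 10).

The generative model
--------------------
* Fixed spatial source maps ``M`` (voxels x latent), shared by all
  subjects; per-subject source strengths ``w_s`` drawn log-normal around 1
  so connectivity varies smoothly across subjects without sign flips.
* BOLD for subject s: ``X_s = M diag(w_s) Z_s + noise_sd * E`` with unit
  variance temporal sources ``Z_s`` regenerated per subject from the seed.
* One latent source (``coupled_source_index``) is linearly coupled to one
  outcome domain: the coupled domain is ``50 + 10 * (r z + sqrt(1-r^2) e)``
  where z is the standardized planted strength, e independent noise, and
  r = ``coupling_r`` is the exact population correlation.
* The three problem domains (Externalizing / Internalizing /
  Dysregulation) share pairwise noise correlation ~0.3; Competence is
  independent — mirroring the usual inter-domain structure of the
  instrument.
* ROI volume = intercept + slope * PMA + Gaussian noise, with the noise SD
  solved analytically so the volume-PMA correlation equals ``target_r``
  (default 0.74).

All randomness flows through named, subject-tagged
:class:`numpy.random.SeedSequence` streams, so every output is
bit-reproducible for a given seed and ``generate_bold`` can regenerate any
single subject independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectome import BoldSeries, write_bold_tsv
from .qc import MotionTrace, write_motion_par

__all__ = [
    "DOMAINS",
    "DEFAULT_ROI_LABELS",
    "CohortConfig",
    "GroundTruth",
    "SubjectRecord",
    "make_ground_truth",
    "make_subject_records",
    "generate_bold",
    "generate_motion_trace",
    "generate_volumes",
    "generate_cohort",
    "write_cohort",
]

DOMAINS = ("Externalizing", "Internalizing", "Dysregulation", "Competence")

DEFAULT_ROI_LABELS = (
    "Anterior lobe L",
    "Anterior lobe R",
    "Central lobe L",
    "Central lobe R",
    "Posterior lobe L",
    "Posterior lobe R",
    "Central vermis",
    "Posterior vermis",
)

# Demographic targets: PMA at scan 42.00 (1.91) weeks, range 38.57-47.43;
# birthweight 3303 (432) g, range 2280-4184.
_PMA_MEAN, _PMA_SD, _PMA_LO, _PMA_HI = 42.00, 1.91, 38.57, 47.43
_BW_MEAN, _BW_SD, _BW_LO, _BW_HI = 3303.0, 432.0, 2280.0, 4184.0

# stream tags for named RNG substreams
_TAG_TRUTH, _TAG_SCORES, _TAG_BOLD, _TAG_MOTION, _TAG_VOLUMES = 11, 12, 13, 14, 15


class ConfigError(ValueError):
    """Invalid cohort configuration; message names the offending field."""


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort."""

    n_subjects: int = 72
    n_voxels: int = 325
    n_volumes: int = 200
    tr_seconds: float = 2.0
    n_latent: int = 6
    coupled_source_index: int = 0
    coupled_domain: str = "Externalizing"
    coupling_r: float = 0.42
    noise_sd: float = 1.0
    strength_log_sd: float = 0.5
    spike_rate: float = 0.02
    spike_mm: float = 0.5
    jitter_mm: float = 0.01
    volume_target_r: float = 0.74
    roi_labels: tuple = DEFAULT_ROI_LABELS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_latent < 1 or self.n_voxels < self.n_latent:
            raise ConfigError("n_voxels/n_latent: need n_voxels >= n_latent >= 1")
        if self.n_volumes <= 4:
            raise ConfigError("n_volumes: must exceed 4")
        if not 0 <= self.coupling_r < 1:
            raise ConfigError("coupling_r: must be in [0, 1)")
        if not 0 <= self.coupled_source_index < self.n_latent:
            raise ConfigError("coupled_source_index: out of range for n_latent")
        if self.coupled_domain not in DOMAINS:
            raise ConfigError(f"coupled_domain: must be one of {DOMAINS}")
        if self.n_subjects < 2:
            raise ConfigError("n_subjects: need at least 2")
        if len(self.roi_labels) != 8:
            raise ConfigError("roi_labels: exactly 8 ROI names required")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd: must be non-negative")
        if not 0 <= self.spike_rate <= 1:
            raise ConfigError("spike_rate: must be a probability")


@dataclass
class GroundTruth:
    """Hidden parameters the generator planted; used to validate recovery."""

    spatial_maps: np.ndarray  # voxels x latent, fixed across subjects
    subject_strengths: np.ndarray  # subjects x latent
    true_scores_linear: np.ndarray  # standardized planted outcome axis
    volume_slopes: np.ndarray  # cm^3 per week, per ROI
    volume_intercepts: np.ndarray  # cm^3, per ROI
    roi_assignment: np.ndarray  # per-voxel ROI label


@dataclass
class SubjectRecord:
    subject_id: str
    sex: int  # 0 = female, 1 = male
    pma_weeks: float
    birthweight_g: float
    domain_scores: dict = field(default_factory=dict)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), *map(int, key))))


def _roi_assignment(config: CohortConfig) -> np.ndarray:
    """Deterministic near-equal contiguous split of voxels over the 8 ROIs."""
    blocks = np.array_split(np.arange(config.n_voxels), len(config.roi_labels))
    labels = np.empty(config.n_voxels, dtype=object)
    for name, block in zip(config.roi_labels, blocks):
        labels[block] = name
    return labels.astype(str)


def _strength_log_sds(config: CohortConfig) -> np.ndarray:
    """Per-source log-SD profile: 1.6x the base for the dominant source,
    then a linear taper from the base down to half of it."""
    s = config.strength_log_sd
    if config.n_latent == 1:
        return np.array([1.6 * s])
    return np.concatenate([[1.6 * s], np.linspace(s, 0.5 * s, config.n_latent - 1)])


def make_ground_truth(config: CohortConfig) -> GroundTruth:
    """Draw the fixed latent structure of one synthetic study."""
    rng = _rng(config.seed, _TAG_TRUTH)
    roi = _roi_assignment(config)
    # Spatially clustered source footprints: each source loads strongly on
    # two "home" ROIs and weakly elsewhere, plus voxel-level scatter.  With
    # overlapping dense footprints the per-source FC patterns are far from
    # orthogonal and PCA cannot separate the sources.
    label_to_idx = {name: i for i, name in enumerate(config.roi_labels)}
    roi_index = np.array([label_to_idx[lab] for lab in roi])
    n_roi = len(config.roi_labels)
    roi_weights = 0.25 * rng.normal(0.0, 1.0, size=(n_roi, config.n_latent))
    for lat in range(config.n_latent):
        homes = [(2 * lat) % n_roi, (2 * lat + 1) % n_roi]
        roi_weights[homes, lat] += 1.6 * rng.choice([-1.0, 1.0], size=2)
    maps = roi_weights[roi_index] + 0.3 * rng.normal(
        0.0, 1.0, size=(config.n_voxels, config.n_latent)
    )
    # Decaying per-source strength variability (dominant mode first),
    # mirroring the sharply decaying variance spectra of empirical
    # gradients; equal variances would leave PCA rotationally degenerate.
    strengths = np.exp(
        rng.normal(0.0, 1.0, size=(config.n_subjects, config.n_latent))
        * _strength_log_sds(config)
    )
    planted = strengths[:, config.coupled_source_index]
    z = (planted - planted.mean()) / planted.std()
    slopes = rng.uniform(0.08, 0.35, size=len(config.roi_labels))
    baseline = rng.uniform(2.5, 6.5, size=len(config.roi_labels))  # cm^3 near term
    intercepts = baseline - slopes * _PMA_MEAN
    return GroundTruth(
        spatial_maps=maps,
        subject_strengths=strengths,
        true_scores_linear=z,
        volume_slopes=slopes,
        volume_intercepts=intercepts,
        roi_assignment=roi,
    )


def make_subject_records(
    config: CohortConfig, truth: GroundTruth
) -> list[SubjectRecord]:
    """Draw covariates and the four outcome t-scores.

    The coupled domain mixes the planted latent axis with independent noise
    at mixing weight ``coupling_r``; the remaining domains are correlated
    noise (pairwise ~0.3 among the three problem domains, Competence
    independent).  Scores are scaled as ``50 + 10 * value`` where the value
    has zero mean and unit variance in the population.
    """
    rng = _rng(config.seed, _TAG_SCORES)
    n = config.n_subjects
    pma = sps.truncnorm.rvs(
        (_PMA_LO - _PMA_MEAN) / _PMA_SD,
        (_PMA_HI - _PMA_MEAN) / _PMA_SD,
        loc=_PMA_MEAN,
        scale=_PMA_SD,
        size=n,
        random_state=rng,
    )
    bw = sps.truncnorm.rvs(
        (_BW_LO - _BW_MEAN) / _BW_SD,
        (_BW_HI - _BW_MEAN) / _BW_SD,
        loc=_BW_MEAN,
        scale=_BW_SD,
        size=n,
        random_state=rng,
    )
    sex = rng.integers(0, 2, size=n)
    # correlated noise base for the four domains
    corr = np.eye(4)
    for a in range(3):
        for b in range(3):
            if a != b:
                corr[a, b] = 0.3
    chol = np.linalg.cholesky(corr)
    base = rng.normal(0.0, 1.0, size=(n, 4)) @ chol.T
    r = config.coupling_r
    coupled_col = DOMAINS.index(config.coupled_domain)
    values = base.copy()
    values[:, coupled_col] = (
        r * truth.true_scores_linear + np.sqrt(1.0 - r**2) * base[:, coupled_col]
    )
    scores = 50.0 + 10.0 * values
    records = []
    for i in range(n):
        records.append(
            SubjectRecord(
                subject_id=f"S{i + 1:04d}",
                sex=int(sex[i]),
                pma_weeks=float(pma[i]),
                birthweight_g=float(bw[i]),
                domain_scores={d: float(scores[i, j]) for j, d in enumerate(DOMAINS)},
            )
        )
    return records


def generate_bold(
    truth: GroundTruth, subject_index: int, config: CohortConfig
) -> BoldSeries:
    """Synthesize one subject's voxels x time BOLD matrix.

    ``X = M diag(w_s) Z_s + noise_sd * E`` with row-standardized (unit
    variance) temporal sources regenerated per subject from the seed.
    """
    if not 0 <= subject_index < config.n_subjects:
        raise ValueError(f"subject_index {subject_index} out of range")
    if config.n_volumes <= config.n_latent:
        raise ValueError(
            "n_volumes must exceed n_latent: temporal sources are unidentifiable"
        )
    rng = _rng(config.seed, _TAG_BOLD, subject_index)
    z = rng.normal(0.0, 1.0, size=(config.n_latent, config.n_volumes))
    z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
    w = truth.subject_strengths[subject_index]
    signal = truth.spatial_maps @ (w[:, None] * z)
    noise = config.noise_sd * rng.normal(0.0, 1.0, size=signal.shape)
    data = signal + noise
    if np.any(data.var(axis=1) == 0):
        raise ValueError("generated a zero-variance voxel row; increase noise_sd")
    return BoldSeries(
        data=data,
        roi_labels=truth.roi_assignment,
        subject_id=f"S{subject_index + 1:04d}",
    )


def generate_motion_trace(
    config: CohortConfig,
    subject_index: int,
    spike_rate: float | None = None,
    spike_mm: float | None = None,
    jitter_mm: float | None = None,
) -> MotionTrace:
    """Six-parameter motion trace with baseline jitter and step spikes.

    A spike is a persistent position step of ``spike_mm`` on one random
    translation axis, so each spike produces one above-threshold framewise
    displacement.  Spiked volumes are drawn Bernoulli(``spike_rate``) from
    volume 1 onward.  Rotational jitter is scaled so its arc-length
    contribution on a 50 mm sphere matches the translational jitter.
    """
    spike_rate = config.spike_rate if spike_rate is None else spike_rate
    spike_mm = config.spike_mm if spike_mm is None else spike_mm
    jitter_mm = config.jitter_mm if jitter_mm is None else jitter_mm
    if not 0 <= spike_rate <= 1:
        raise ValueError("spike_rate must be a probability")
    if spike_mm < 0:
        raise ValueError("spike_mm must be non-negative")
    if jitter_mm < 0:
        raise ValueError("jitter_mm must be non-negative")
    rng = _rng(config.seed, _TAG_MOTION, subject_index)
    t = config.n_volumes
    params = np.zeros((t, 6))
    if jitter_mm > 0:
        params[:, :3] = rng.normal(0.0, jitter_mm, size=(t, 3))
        params[:, 3:] = rng.normal(0.0, jitter_mm / 50.0, size=(t, 3))
    spikes = rng.random(t - 1) < spike_rate
    axes = rng.integers(0, 3, size=t - 1)
    signs = rng.choice([-1.0, 1.0], size=t - 1)
    steps = np.zeros((t, 3))
    for vol in np.flatnonzero(spikes):
        steps[vol + 1, axes[vol]] += signs[vol] * spike_mm
    params[:, :3] += np.cumsum(steps, axis=0)
    return MotionTrace(params=params, subject_id=f"S{subject_index + 1:04d}")


def generate_volumes(
    records: list[SubjectRecord],
    truth: GroundTruth,
    target_r: float | None = None,
    config: CohortConfig | None = None,
) -> pd.DataFrame:
    """ROI volumes growing linearly with PMA at a controlled correlation.

    volume = intercept + slope * PMA + eps, with the noise SD solved from
    ``r^2 = s^2 var(PMA) / (s^2 var(PMA) + sd_eps^2)`` so the volume-PMA
    correlation equals ``target_r`` (``target_r = 1`` gives the exact
    noiseless case).
    """
    if config is None:
        raise ValueError("config is required")
    target_r = config.volume_target_r if target_r is None else target_r
    if not 0 < target_r <= 1:
        raise ValueError("target_r must be in (0, 1]")
    pma = np.array([rec.pma_weeks for rec in records])
    sd_pma = pma.std()
    if sd_pma <= 1e-12:
        raise ValueError("degenerate PMA variance: cannot calibrate volume noise")
    rng = _rng(config.seed, _TAG_VOLUMES)
    data = {"subject_id": [rec.subject_id for rec in records]}
    for j, roi in enumerate(config.roi_labels):
        slope = truth.volume_slopes[j]
        noise_sd = (
            0.0
            if target_r == 1
            else abs(slope) * sd_pma * np.sqrt(1.0 / target_r**2 - 1.0)
        )
        vols = truth.volume_intercepts[j] + slope * pma
        vols = vols + rng.normal(0.0, noise_sd, size=len(records)) if noise_sd else vols
        data[roi] = vols
    return pd.DataFrame(data)


def generate_cohort(config: CohortConfig):
    """Generate the full synthetic study.

    Returns
    -------
    (records, bolds, motions, volumes, truth)
        Subject covariate/outcome records, per-subject BOLD matrices,
        per-subject motion traces, the subject x 8-ROI volume table, and
        the planted ground truth.
    """
    truth = make_ground_truth(config)
    records = make_subject_records(config, truth)
    bolds = [generate_bold(truth, i, config) for i in range(config.n_subjects)]
    motions = [generate_motion_trace(config, i) for i in range(config.n_subjects)]
    volumes = generate_volumes(records, truth, config=config)
    return records, bolds, motions, volumes, truth


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {
            "subject_id": rec.subject_id,
            "sex": rec.sex,
            "pma_weeks": rec.pma_weeks,
            "birthweight_g": rec.birthweight_g,
        }
        row.update(rec.domain_scores)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(outdir: str | Path, config: CohortConfig) -> dict:
    """Generate and persist a cohort; returns paths of everything written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, bolds, motions, volumes, truth = generate_cohort(config)
    subjects = records_to_frame(records)
    subjects.to_csv(outdir / "subjects.csv", index=False)
    volumes.to_csv(outdir / "volumes.csv", index=False)
    paths = {
        "subjects": str(outdir / "subjects.csv"),
        "volumes": str(outdir / "volumes.csv"),
        "bold": [],
        "motion": [],
    }
    for rec, bold, motion in zip(records, bolds, motions):
        bold_path = outdir / f"bold_{rec.subject_id}.tsv"
        par_path = outdir / f"motion_{rec.subject_id}.par"
        write_bold_tsv(bold, bold_path)
        write_motion_par(motion, par_path)
        paths["bold"].append(str(bold_path))
        paths["motion"].append(str(par_path))
    truth_json = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "spatial_maps": truth.spatial_maps.tolist(),
        "subject_strengths": truth.subject_strengths.tolist(),
        "true_scores_linear": truth.true_scores_linear.tolist(),
        "volume_slopes": truth.volume_slopes.tolist(),
        "volume_intercepts": truth.volume_intercepts.tolist(),
        "roi_assignment": truth.roi_assignment.tolist(),
    }
    (outdir / "truth.json").write_text(json.dumps(truth_json))
    paths["truth"] = str(outdir / "truth.json")
    return paths
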