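"""Seeded synthetic cohorts with planted diagnosis and nuisance effects.

The generators emulate a multi-site resting-state FC case–control study: an
attribute table (diagnosis, three one-hot site flags, age, sex, eye
condition, three medication flags — 10 columns), an FC matrix in which a
small planted subset of connections carries a true group-mean difference
while other subsets are driven by nuisance variables, and per-subject ROI
time series with controlled correlation structure and motion spikes.

FC values are built on a latent (Fisher-z-like) Gaussian scale and squashed
through tanh, which keeps them in [-1, 1] without altering rank order; with
the default noise scale the map stays in its near-linear regime, so planted
standardized mean differences survive the squashing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from fcbiomarker.scca import ATTRIBUTE_COLUMNS

__all__ = [
    "GroundTruth",
    "MotionSpec",
    "generate_attributes",
    "generate_fc_cohort",
    "generate_timeseries",
    "planted_cohort",
    "save_cohort",
]


@dataclass
class GroundTruth:
    """Which FC columns carry which planted effects.

    ``nuisance_map`` maps an attribute column name (any of the non-diagnosis
    columns) to ``(indices, per_unit_effect)``: the listed FC columns receive
    ``per_unit_effect * value`` on the latent scale, where ``value`` is the
    subject's raw attribute value for binary columns and the z-scored value
    for age.
    """

    diagnosis_fc_indices: np.ndarray
    effect_size: float
    nuisance_map: dict[str, tuple[np.ndarray, float]] = field(default_factory=dict)
    noise_sd: float = 0.1
    #: seed of the per-column FC baselines: baselines encode (shared) biology,
    #: so cohorts generated from the same ground truth share them
    baseline_seed: int = 0

    def __post_init__(self) -> None:
        self.diagnosis_fc_indices = np.asarray(self.diagnosis_fc_indices, dtype=int)
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def max_index(self) -> int:
        idx = [self.diagnosis_fc_indices.max(initial=-1)]
        for indices, _ in self.nuisance_map.values():
            idx.append(np.asarray(indices).max(initial=-1))
        return int(max(idx))

    def to_json(self, path: str) -> None:
        payload = {
            "diagnosis_fc_indices": self.diagnosis_fc_indices.tolist(),
            "effect_size": self.effect_size,
            "noise_sd": self.noise_sd,
            "baseline_seed": self.baseline_seed,
            "nuisance_map": {
                k: {"indices": np.asarray(v[0]).tolist(), "per_unit_effect": v[1]}
                for k, v in self.nuisance_map.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class MotionSpec:
    """Head-motion profile: baseline jitter plus displacement jumps."""

    n_frames: int
    spike_frames: tuple[int, ...] = ()
    spike_magnitude: float = 1.0
    baseline_jitter_sd: float = 0.02

    def __post_init__(self) -> None:
        if any(not 0 <= t < self.n_frames for t in self.spike_frames):
            raise ValueError("spike frames out of range")
        if self.spike_magnitude < 0 or self.baseline_jitter_sd < 0:
            raise ValueError("magnitudes must be nonnegative")


def generate_attributes(
    n_subjects: int,
    site_proportions: tuple[float, float, float] = (0.4, 0.4, 0.2),
    asd_fraction: float = 0.5,
    seed: int = 0,
    age_range: tuple[float, float] = (20.0, 45.0),
    male_fraction: float = 0.7,
    eye_open_fraction: float = 0.5,
    medication_rates: tuple[float, float] = (0.4, 0.0),
    control_only_sites: tuple[int, ...] = (),
    exact_balance: bool = False,
) -> pd.DataFrame:
    """Generate an n x 10 subject-attribute table.

    Columns: diagnosis (0/1), three one-hot site flags, age (years, uniform
    over ``age_range``), sex (1 = male), eye condition (1 = open), three
    medication flags. ``medication_rates`` gives the per-flag Bernoulli rate
    for cases and controls respectively (the default medicates only cases,
    mirroring clinical cohorts; set both equal for diagnosis-independent
    medication). ``control_only_sites`` lists 0-based site indices that
    recruit no cases, emulating a control-only acquisition site.

    ``exact_balance=True`` fixes the case count to ``round(n *
    asd_fraction)`` (assigned by a seeded permutation) instead of per-subject
    Bernoulli draws — the designed-experiment convention for calibration
    cohorts, where the chance accuracy level must be exactly
    ``max(asd_fraction, 1 - asd_fraction)``.
    """
    props = np.asarray(site_proportions, dtype=float)
    if len(props) != 3 or np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("site proportions must be 3 nonnegative values summing to 1")
    if n_subjects < 4:
        raise ValueError("need at least 4 subjects")
    rng = np.random.default_rng(seed)
    site = rng.choice(3, size=n_subjects, p=props)
    if exact_balance:
        n_cases = round(n_subjects * asd_fraction)
        diagnosis = np.zeros(n_subjects, dtype=int)
        diagnosis[rng.permutation(n_subjects)[:n_cases]] = 1
    else:
        diagnosis = (rng.random(n_subjects) < asd_fraction).astype(int)
    for s in control_only_sites:
        diagnosis[site == s] = 0
    sites = np.zeros((n_subjects, 3), dtype=int)
    sites[np.arange(n_subjects), site] = 1
    age = rng.uniform(*age_range, size=n_subjects)
    sex = (rng.random(n_subjects) < male_fraction).astype(int)
    eye = (rng.random(n_subjects) < eye_open_fraction).astype(int)
    case_rate, control_rate = medication_rates
    rates = np.where(diagnosis == 1, case_rate, control_rate)
    meds = (rng.random((n_subjects, 3)) < rates[:, None]).astype(int)
    table = pd.DataFrame(
        np.column_stack([diagnosis, sites, age, sex, eye, meds]),
        columns=list(ATTRIBUTE_COLUMNS),
    )
    for col in table.columns:
        if col != "age":
            table[col] = table[col].astype(int)
    return table


def generate_fc_cohort(
    attributes: pd.DataFrame,
    n_fc: int,
    truth: GroundTruth,
    seed: int = 0,
    baseline_sd: float = 0.2,
) -> tuple[np.ndarray, GroundTruth]:
    """Generate an n x n_fc FC matrix with the planted effects of ``truth``.

    On the latent scale each FC value is a per-column baseline (N(0,
    ``baseline_sd``)) plus ``effect_size * noise_sd`` for diagnosed subjects
    at the planted diagnosis columns, plus the nuisance contributions, plus
    N(0, ``noise_sd``) noise; the matrix returned is tanh of that latent
    value. The baseline profile is drawn from ``truth.baseline_seed``, not
    ``seed``, so independently sampled cohorts from the same ground truth
    share their per-column baselines (as real cohorts share biology).
    """
    if truth.max_index() >= n_fc:
        raise IndexError("planted index outside the FC vector")
    rng = np.random.default_rng(seed)
    n = len(attributes)
    baseline = np.random.default_rng(truth.baseline_seed).normal(
        0.0, baseline_sd, size=n_fc
    )
    latent = np.tile(baseline, (n, 1))
    latent += rng.normal(0.0, truth.noise_sd, size=(n, n_fc))
    diagnosis = attributes["diagnosis"].to_numpy(dtype=float)
    if len(truth.diagnosis_fc_indices):
        latent[:, truth.diagnosis_fc_indices] += (
            truth.effect_size * truth.noise_sd * diagnosis[:, None]
        )
    for col, (indices, per_unit) in truth.nuisance_map.items():
        values = attributes[col].to_numpy(dtype=float)
        if col == "age":
            sd = values.std()
            values = (values - values.mean()) / (sd if sd > 0 else 1.0)
        indices = np.asarray(indices, dtype=int)
        latent[:, indices] += per_unit * values[:, None]
    return np.tanh(latent), truth


def _smooth_lowpass(x: np.ndarray, cutoff_frac: float = 0.05) -> np.ndarray:
    b, a = signal.butter(2, cutoff_frac)
    return signal.filtfilt(b, a, x, axis=0, padlen=min(15, x.shape[0] - 1))


def generate_timeseries(
    n_frames: int,
    n_regions: int,
    target_correlation: np.ndarray | None = None,
    motion: MotionSpec | None = None,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Generate one subject's ROI series, motion parameters, tissue signals.

    The ROI block is multivariate normal with the requested correlation
    (must be symmetric PSD with unit diagonal; identity if omitted). Motion
    is white jitter per parameter plus persistent displacement jumps at
    ``spike_frames``; tissue signals are three independent low-pass filtered
    noise series.
    """
    rng = np.random.default_rng(seed)
    if target_correlation is None:
        target_correlation = np.eye(n_regions)
    c = np.asarray(target_correlation, dtype=float)
    if c.shape != (n_regions, n_regions) or not np.allclose(c, c.T):
        raise ValueError("target correlation must be symmetric n_regions^2")
    if not np.allclose(np.diag(c), 1.0):
        raise ValueError("target correlation needs a unit diagonal")
    eigvals = np.linalg.eigvalsh(c)
    if eigvals.min() < -1e-10:
        raise ValueError("target correlation must be positive semidefinite")
    l = np.linalg.cholesky(c + 1e-12 * np.eye(n_regions))
    data = rng.standard_normal((n_frames, n_regions)) @ l.T
    motion = motion or MotionSpec(n_frames=n_frames)
    if motion.n_frames != n_frames:
        raise ValueError("motion spec frame count mismatch")
    params = rng.normal(0.0, motion.baseline_jitter_sd, size=(n_frames, 6))
    # rotations are radians; keep their arc-length displacement (50 mm
    # sphere convention) on the same scale as the translational jitter
    params[:, 3:] /= 50.0
    for t in motion.spike_frames:
        params[t:, :3] += motion.spike_magnitude  # persistent translation jump
    tissue = _smooth_lowpass(rng.standard_normal((n_frames, 3)))
    return {"data": data, "motion": params, "tissue_signals": tissue}


def planted_cohort(
    n_subjects: int = 360,
    n_fc: int = 2000,
    n_diagnosis_fc: int = 15,
    n_site_fc: int = 50,
    effect_size: float = 1.0,
    site_effect: float | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
    **attribute_kwargs,
) -> tuple[pd.DataFrame, np.ndarray, GroundTruth]:
    """Convenience cohort: planted diagnosis FCs plus site-linked FCs.

    The first ``n_diagnosis_fc`` columns carry the diagnosis effect; the
    next ``n_site_fc`` columns are driven by the site-B flag (a pure
    acquisition-site artifact, independent of diagnosis by construction
    unless site/diagnosis confounding is requested through
    ``attribute_kwargs``). ``site_effect`` defaults to ``noise_sd`` per unit.
    """
    attrs = generate_attributes(n_subjects, seed=seed, **attribute_kwargs)
    diag_idx = np.arange(n_diagnosis_fc)
    site_idx = np.arange(n_diagnosis_fc, n_diagnosis_fc + n_site_fc)
    truth = GroundTruth(
        diagnosis_fc_indices=diag_idx,
        effect_size=effect_size,
        nuisance_map={"site_b": (site_idx, noise_sd if site_effect is None else site_effect)},
        noise_sd=noise_sd,
    )
    fc, truth = generate_fc_cohort(attrs, n_fc, truth, seed=seed + 1)
    return attrs, fc, truth


def save_cohort(
    out_dir: str | Path,
    attributes: pd.DataFrame,
    fc_matrix: np.ndarray,
    truth: GroundTruth | None = None,
) -> None:
    """Write a cohort to disk: attribute CSV, FC TSV, ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    attributes.to_csv(out / "attributes.csv", index=False)
    np.savetxt(out / "fc_matrix.tsv", fc_matrix, delimiter="\t")
    if truth is not None:
        truth.to_json(str(out / "ground_truth.json"))
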