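"""Desk-scale longitudinal progressive-disease cohort simulator.

The simulator emulates the statistical structure that the progressive risk
formulation assumes in a knee-osteoarthritis-like study, without any real
imaging data:

* every subject carries a monotone latent severity ``s(t) = s0 + rate * t``
  (progressive disease: severity never declines);
* the terminal event (the joint-replacement analog) occurs when severity
  first crosses a threshold ``theta``; subjects with ``rate == 0`` never
  progress and end the study event-free;
* severity is observed through either a feature vector (``w * severity``
  plus Gaussian noise) or a synthetic grayscale "radiograph" in which the
  joint-space gap between two bright bands narrows with severity;
* an ordinal 0-4 grade (the Kellgren-Lawrence analog) is a fixed binning of
  the latent severity;
* subjects are drawn in demographically matched (progressor, stable) couples
  so the downstream exact-covariate case-control matching has support;
* visits are annual with absorbing drop-out, so "last available scan"
  selection is non-trivial, and no scan exists at or after the event.

Event dates are recorded on a quarter-year grid (clinic scheduling
granularity); this gives the progression group positive mass even at the
1-year horizon, where an event must fall exactly one visit-gap after the
selected follow-up scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SubjectTrajectory",
    "SimConfig",
    "Cohort",
    "severity_at",
    "event_time",
    "grade_of",
    "render_scan",
    "simulate_cohort",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = [
    "subject_id",
    "scan_time_years",
    "payload_path",
    "grade",
    "age",
    "sex",
    "ethnicity",
    "bmi",
    "event_time_years",
]

ETHNICITIES = ("A", "B", "C")


@dataclass(frozen=True)
class SubjectTrajectory:
    """One subject's latent disease course and visit schedule."""

    subject_id: str
    s0: float
    rate: float
    theta: float
    age: int
    sex: int
    ethnicity: str
    bmi: float
    scan_times: tuple = ()

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("baseline severity must be >= 0")
        if self.rate < 0:
            raise ValueError("severity slope must be >= 0 (progressive disease)")
        if self.theta <= 0:
            raise ValueError("event threshold must be > 0")
        ts = tuple(float(t) for t in self.scan_times)
        if ts:
            if ts[0] != 0.0:
                raise ValueError("scan schedule must start at baseline (t=0)")
            if any(b <= a for a, b in zip(ts, ts[1:])):
                raise ValueError("scan times must be strictly increasing")
        object.__setattr__(self, "scan_times", ts)


@dataclass(frozen=True)
class SimConfig:
    """Cohort-simulation settings.

    Defaults describe a 400-subject matched cohort with annual visits over
    9 years, half stable (rate 0) and half progressing at 0.2-1.0 severity
    units/year toward the event threshold of 4 (the top of the grade scale),
    observed through 8-dimensional noisy features.
    """

    n_subjects: int = 400
    s0_range: tuple = (0.0, 2.5)
    progressor_fraction: float = 0.5
    rate_range: tuple = (0.2, 1.0)
    theta: float = 4.0
    grade_cuts: tuple = (1.0, 2.0, 3.0, 4.0)
    noise_sd: float = 0.5
    payload: str = "features"  # "features" | "image"
    n_features: int = 8
    image_size: int = 32
    severity_max: float = 5.0  # severity at which the joint-space gap closes
    horizons: tuple = (1, 2, 4)
    n_visits: int = 10  # annual visits at years 0..n_visits-1
    dropout: float = 0.08  # per-visit absorbing drop-out probability
    event_resolution: float = 0.25  # event dates recorded on this grid
    age_range: tuple = (50, 64)
    bmi_log_mean: float = 3.35  # lognormal BMI, median ~28.5 kg/m^2
    bmi_log_sd: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.payload not in ("features", "image"):
            raise ValueError(f"unknown payload kind {self.payload!r}")
        if self.n_visits < 1 or self.n_features < 1 or self.image_size < 8:
            raise ValueError("counts must be positive (image_size >= 8)")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if tuple(sorted(self.grade_cuts)) != tuple(self.grade_cuts) or len(self.grade_cuts) != 4:
            raise ValueError("grade_cuts must be 4 increasing severity cut points")


@dataclass
class Cohort:
    """In-memory simulated cohort: manifest rows plus payload arrays."""

    manifest: pd.DataFrame
    payloads: dict
    config: SimConfig

    @property
    def n_subjects(self) -> int:
        return self.manifest["subject_id"].nunique()


def severity_at(traj: SubjectTrajectory, t: float) -> float:
    """Latent severity at ``t`` years from baseline: ``s0 + rate * t``."""
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    return traj.s0 + traj.rate * t


def event_time(traj: SubjectTrajectory):
    """First time severity reaches the threshold; ``None`` when censored.

    Closed form ``(theta - s0) / rate``; 0 when already past threshold at
    baseline; a non-progressor (rate 0) below threshold never crosses.
    """
    if traj.s0 >= traj.theta:
        return 0.0
    if traj.rate == 0.0:
        return None
    return (traj.theta - traj.s0) / traj.rate


def grade_of(severity: float, config: SimConfig):
    """Ordinal 0-4 grade: severity binned by the four fixed cut points.

    Bins are left-closed on the upper side: a severity exactly at a cut
    point falls in the higher grade.  Non-decreasing in severity.
    """
    sev = np.asarray(severity, dtype=float)
    if np.any(sev < 0):
        raise ValueError("severity must be >= 0")
    g = np.searchsorted(np.asarray(config.grade_cuts, dtype=float), sev, side="right")
    return g if g.ndim else int(g)


def _band_rows(cfg: SimConfig, severity: float):
    """Row spans of the two bright bands for the image renderer."""
    size = cfg.image_size
    thickness = max(1, size // 8)
    gap0 = size // 2
    gap = int(round(gap0 * max(0.0, 1.0 - severity / cfg.severity_max)))
    center = size // 2
    top_lo = max(0, center - gap // 2 - thickness)
    top_hi = max(0, center - gap // 2)
    bot_lo = min(size, center + (gap + 1) // 2)
    bot_hi = min(size, bot_lo + thickness)
    return (top_lo, top_hi), (bot_lo, bot_hi), gap


def render_scan(severity: float, cfg: SimConfig, seed) -> np.ndarray:
    """Render one scan payload for a given latent severity.

    Feature mode: ``x = w * severity + eps`` with a fixed unit direction
    ``w`` (deterministic per configuration) and ``eps ~ N(0, noise_sd^2)``.
    Image mode: a square grayscale array in [0, 1] with two bright
    horizontal bands whose gap (the joint-space analog) shrinks linearly
    with severity, plus pixelwise Gaussian noise.  Deterministic given
    ``seed``.
    """
    if severity < 0:
        raise ValueError("severity must be >= 0")
    rng = np.random.default_rng(seed)
    if cfg.payload == "features":
        w = feature_direction(cfg)
        return w * severity + rng.normal(0.0, cfg.noise_sd, size=cfg.n_features)
    (t_lo, t_hi), (b_lo, b_hi), _ = _band_rows(cfg, severity)
    img = np.zeros((cfg.image_size, cfg.image_size), dtype=float)
    img[t_lo:t_hi, :] = 1.0
    img[b_lo:b_hi, :] = 1.0
    if cfg.noise_sd > 0:
        # image noise kept modest relative to unit band intensity
        img += rng.normal(0.0, 0.1 * cfg.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def feature_direction(cfg: SimConfig) -> np.ndarray:
    """Fixed unit vector along which severity is encoded in feature mode."""
    w = np.random.default_rng(20240117).normal(size=cfg.n_features)
    return w / np.linalg.norm(w)


def _quantize_event(t: float, resolution: float) -> float:
    """Record an event date on the scheduling grid, never before the true
    crossing (ceil)."""
    if resolution <= 0:
        return t
    return math.ceil(t / resolution - 1e-9) * resolution


def _draw_demographics(rng: np.random.Generator, cfg: SimConfig):
    age = int(rng.integers(cfg.age_range[0], cfg.age_range[1] + 1))
    sex = int(rng.integers(0, 2))
    ethnicity = ETHNICITIES[int(rng.integers(0, len(ETHNICITIES)))]
    bmi = float(np.round(np.exp(rng.normal(cfg.bmi_log_mean, cfg.bmi_log_sd)), 1))
    return age, sex, ethnicity, bmi


def _draw_trajectories(cfg: SimConfig, rng: np.random.Generator):
    """Draw subjects in matched (progressor, stable) couples.

    The couple shares age, sex and ethnicity; the stable member's BMI is
    jittered within +-5% so the 10%-tolerance matching constraint can hold.
    """
    trajs = []
    n_pairs, leftover = divmod(cfg.n_subjects, 2)
    idx = 0
    for _ in range(n_pairs):
        age, sex, eth, bmi = _draw_demographics(rng, cfg)
        bmi2 = float(np.round(bmi * (1.0 + rng.uniform(-0.05, 0.05)), 1))
        is_prog_first = bool(rng.integers(0, 2))
        for k in range(2):
            progressor = (k == 0) == is_prog_first
            s0 = float(rng.uniform(*cfg.s0_range))
            rate = float(rng.uniform(*cfg.rate_range)) if progressor else 0.0
            trajs.append(
                SubjectTrajectory(
                    subject_id=f"S{idx:04d}",
                    s0=s0,
                    rate=rate,
                    theta=cfg.theta,
                    age=age,
                    sex=sex,
                    ethnicity=eth,
                    bmi=bmi if k == 0 else bmi2,
                )
            )
            idx += 1
    for _ in range(leftover):
        age, sex, eth, bmi = _draw_demographics(rng, cfg)
        s0 = float(rng.uniform(*cfg.s0_range))
        trajs.append(
            SubjectTrajectory(
                subject_id=f"S{idx:04d}", s0=s0, rate=0.0, theta=cfg.theta,
                age=age, sex=sex, ethnicity=eth, bmi=bmi,
            )
        )
        idx += 1
    return trajs


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Simulate a full cohort manifest with rendered payloads.

    Visit schedule: annual visits at years 0..n_visits-1; after baseline,
    each subsequent visit is missed for good with probability ``dropout``
    (absorbing).  Scans exist only strictly before the recorded event date.
    The event is observed iff it falls before both drop-out and the end of
    the study; otherwise the subject is censored at their last attended
    visit.  Subjects already past threshold at baseline (prevalent cases)
    are excluded, mirroring the usual baseline-event exclusion.  Fully
    reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng([cfg.seed, 101])
    trajs = _draw_trajectories(cfg, rng)

    rows = []
    payloads = {}
    study_end = float(cfg.n_visits - 1)
    for si, traj in enumerate(trajs):
        true_event = event_time(traj)
        recorded = None
        if true_event is not None:
            recorded = _quantize_event(true_event, cfg.event_resolution)
            if recorded <= 0.0:
                continue  # prevalent at baseline: excluded

        # absorbing drop-out: first missed annual visit ends follow-up
        dropout_at = study_end + 1.0
        for year in range(1, cfg.n_visits):
            if rng.uniform() < cfg.dropout:
                dropout_at = float(year)
                break

        observed_event = (
            recorded is not None and recorded <= study_end and recorded < dropout_at
        )
        horizon_time = min(
            dropout_at, recorded if recorded is not None else np.inf, study_end + 1.0
        )
        visit_times = [float(y) for y in range(cfg.n_visits) if y < horizon_time]
        if not visit_times:
            continue

        for k, t in enumerate(visit_times):
            sev = severity_at(traj, t)
            key = f"{traj.subject_id}/{k}"
            payloads[key] = render_scan(
                sev, cfg, seed=[cfg.seed, 7, si, k]
            )
            rows.append(
                {
                    "subject_id": traj.subject_id,
                    "scan_time_years": t,
                    "payload_path": key,
                    "grade": grade_of(sev, cfg),
                    "age": traj.age,
                    "sex": traj.sex,
                    "ethnicity": traj.ethnicity,
                    "bmi": traj.bmi,
                    "event_time_years": recorded if observed_event else np.nan,
                }
            )

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return Cohort(manifest=manifest, payloads=payloads, config=cfg)
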