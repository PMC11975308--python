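"""Cohort preparation: horizon labels, scan-pair selection, case-control
matching, and subject-level nested cross-validation splits.

Conventions (all documented in docs/methods.md):

* Horizon labels are inclusive at the boundary: an event exactly ``h`` years
  after a scan counts positive.  A label is *undefined* (the scan is dropped
  at that horizon) when the subject is censored before ``scan_time + h``.
* For subjects with an observed event, the training scan pair is the
  baseline scan plus the latest follow-up scan acquired 1-4 years before the
  event; event-free subjects contribute the baseline plus their latest
  follow-up scan whose label at the horizon is still defined.
* Case-control matching requires identical integer age (optionally widened),
  identical sex and ethnicity, and a control BMI within 10% of the case's
  BMI; it is solved as maximum-cardinality bipartite matching, so the result
  does not depend on subject order.
* Nested splits: 7 outer folds x 6 inner folds, stratified by case/control
  at the subject level, yielding 42 (train, val, test) assignments.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

__all__ = [
    "ScanRecord",
    "PairSet",
    "PairSample",
    "HorizonConfig",
    "SplitPlan",
    "MatchResult",
    "label_for_horizon",
    "select_training_scans",
    "build_pairs",
    "match_case_control",
    "make_nested_splits",
    "scans_by_subject",
    "records_from_manifest",
]

logger = logging.getLogger(__name__)

CASE_PAIR_WINDOW = (1.0, 4.0)  # eligible years between follow-up scan and event


@dataclass(frozen=True)
class ScanRecord:
    """One scan of one knee, with subject-level context attached."""

    subject_id: str
    scan_time_years: float
    payload_ref: str
    grade: int
    age: int
    sex: int
    ethnicity: str
    bmi: float
    event_time_years: float | None = None  # None = censored
    follow_up_years: float = 0.0  # subject's last attended visit

    def __post_init__(self) -> None:
        if self.scan_time_years < 0:
            raise ValueError("scan_time_years must be >= 0")
        if not 0 <= int(self.grade) <= 4:
            raise ValueError(f"grade must be in 0..4, got {self.grade}")
        if self.event_time_years is not None and self.event_time_years < 0:
            raise ValueError("event_time_years must be >= 0")

    @property
    def is_case(self) -> bool:
        return self.event_time_years is not None


class PairSet(str, enum.Enum):
    """Progression status of a training scan pair."""

    SET1_PROGRESSION = "set1"  # negative -> positive
    SET2_STABLE_NEG = "set2"  # negative -> negative
    SET3_STABLE_POS = "set3"  # positive -> positive
    SINGLE = "single"  # only the baseline scan usable


@dataclass(frozen=True)
class HorizonConfig:
    """Prediction window in years; the boundary is inclusive."""

    horizon_years: float

    def __post_init__(self) -> None:
        if self.horizon_years <= 0:
            raise ValueError("horizon must be > 0")


@dataclass(frozen=True)
class PairSample:
    """An ordered (scan1, scan2) training unit with horizon labels.

    ``scan2`` and ``y2`` are ``None`` for single-scan subjects.
    """

    scan1: ScanRecord
    scan2: ScanRecord | None
    y1: int
    y2: int | None
    horizon: float
    set_id: PairSet

    def __post_init__(self) -> None:
        if self.scan1.scan_time_years != 0.0:
            raise ValueError("scan1 must be the baseline scan (t=0)")
        if self.scan2 is not None:
            if self.scan2.scan_time_years <= self.scan1.scan_time_years:
                raise ValueError("scan2 must be strictly later than scan1")
            if (self.y1, self.y2) == (1, 0):
                raise ValueError("labels cannot regress from 1 to 0")
            expected = {
                (0, 1): PairSet.SET1_PROGRESSION,
                (0, 0): PairSet.SET2_STABLE_NEG,
                (1, 1): PairSet.SET3_STABLE_POS,
            }[(self.y1, self.y2)]
            if self.set_id is not expected:
                raise ValueError(f"set_id {self.set_id} inconsistent with labels")
        elif self.set_id is not PairSet.SINGLE:
            raise ValueError("pairs without scan2 must be SINGLE")


def label_for_horizon(scan: ScanRecord, h: HorizonConfig | float):
    """Binary event-within-horizon label; ``None`` when undefined.

    1 if the event falls within ``h`` years of the scan (inclusive); 0 if the
    event is known to fall later, or follow-up extends at least ``h`` years
    past the scan without an event; undefined otherwise (censored too early).
    """
    h = h.horizon_years if isinstance(h, HorizonConfig) else float(h)
    if scan.event_time_years is not None:
        return 1 if scan.event_time_years - scan.scan_time_years <= h else 0
    if scan.follow_up_years - scan.scan_time_years >= h:
        return 0
    return None


def select_training_scans(scans, h: HorizonConfig | float):
    """Build the training :class:`PairSample` for one subject's scans.

    ``scans``: all of one subject's scans.  Returns ``None`` when the subject
    is unusable at this horizon (no baseline scan, or baseline label
    undefined).
    """
    h_years = h.horizon_years if isinstance(h, HorizonConfig) else float(h)
    scans = sorted(scans, key=lambda s: s.scan_time_years)
    if not scans or scans[0].scan_time_years != 0.0:
        sid = scans[0].subject_id if scans else "<empty>"
        logger.warning("subject %s has no baseline scan; skipped", sid)
        return None
    scan1 = scans[0]
    y1 = label_for_horizon(scan1, h_years)
    if y1 is None:
        return None

    followups = [s for s in scans[1:]]
    scan2 = None
    if scan1.is_case:
        event = scan1.event_time_years
        lo, hi = CASE_PAIR_WINDOW
        eligible = [s for s in followups if lo <= event - s.scan_time_years <= hi]
        if eligible:
            scan2 = eligible[-1]
    else:
        eligible = [s for s in followups if label_for_horizon(s, h_years) is not None]
        if eligible:
            scan2 = eligible[-1]

    if scan2 is None:
        return PairSample(scan1, None, y1, None, h_years, PairSet.SINGLE)
    y2 = label_for_horizon(scan2, h_years)
    if y2 is None:  # case scan2 1-4y pre-event always has y2 defined; guard anyway
        return PairSample(scan1, None, y1, None, h_years, PairSet.SINGLE)
    set_id = {
        (0, 1): PairSet.SET1_PROGRESSION,
        (0, 0): PairSet.SET2_STABLE_NEG,
        (1, 1): PairSet.SET3_STABLE_POS,
    }[(y1, y2)]
    return PairSample(scan1, scan2, y1, y2, h_years, set_id)


def records_from_manifest(manifest: pd.DataFrame):
    """Typed :class:`ScanRecord` list from a manifest frame, with per-subject
    follow-up (last attended visit) filled in."""
    records = []
    follow_up = manifest.groupby("subject_id")["scan_time_years"].max()
    for row in manifest.itertuples(index=False):
        ev = row.event_time_years
        ev = None if pd.isna(ev) else float(ev)
        records.append(
            ScanRecord(
                subject_id=str(row.subject_id),
                scan_time_years=float(row.scan_time_years),
                payload_ref=str(row.payload_path),
                grade=int(row.grade),
                age=int(row.age),
                sex=int(row.sex),
                ethnicity=str(row.ethnicity),
                bmi=float(row.bmi),
                event_time_years=ev,
                follow_up_years=float(follow_up[row.subject_id]),
            )
        )
    return records


def scans_by_subject(records):
    by_subject: dict[str, list[ScanRecord]] = {}
    for rec in records:
        by_subject.setdefault(rec.subject_id, []).append(rec)
    return {
        sid: sorted(scans, key=lambda s: s.scan_time_years)
        for sid, scans in by_subject.items()
    }


def build_pairs(manifest: pd.DataFrame, horizons, subject_ids=None):
    """All usable :class:`PairSample` units per horizon.

    Returns ``{horizon: [PairSample, ...]}`` restricted to ``subject_ids``
    when given.
    """
    by_subject = scans_by_subject(records_from_manifest(manifest))
    if subject_ids is not None:
        keep = set(subject_ids)
        by_subject = {s: v for s, v in by_subject.items() if s in keep}
    out = {}
    for h in horizons:
        pairs = []
        for sid in sorted(by_subject):
            sample = select_training_scans(by_subject[sid], h)
            if sample is not None:
                pairs.append(sample)
        out[float(h)] = pairs
    return out


@dataclass(frozen=True)
class MatchResult:
    """Outcome of case-control matching."""

    pairs: tuple  # ((case_id, control_id), ...)
    unmatched_cases: tuple
    unmatched_controls: tuple


def _match_compatible(case, control, bmi_tol, age_tol):
    return (
        abs(case.age - control.age) <= age_tol
        and case.sex == control.sex
        and case.ethnicity == control.ethnicity
        and abs(case.bmi - control.bmi) <= bmi_tol * case.bmi
    )


def match_case_control(manifest: pd.DataFrame, bmi_tol=0.10, age_tol=0) -> MatchResult:
    """One-to-one case-control matching on baseline demographics.

    Compatibility: age within ``age_tol`` years (0 = identical integer age),
    identical sex and ethnicity, control BMI within ``bmi_tol`` (fraction of
    the *case's* BMI).  Solved as maximum-cardinality bipartite matching so
    that no matchable case is stranded by greedy ordering.
    """
    if manifest.empty:
        return MatchResult((), (), ())
    baseline = (
        manifest.sort_values("scan_time_years").groupby("subject_id").head(1)
    )
    recs = records_from_manifest(baseline)
    cases = sorted((r for r in recs if r.is_case), key=lambda r: r.subject_id)
    controls = sorted((r for r in recs if not r.is_case), key=lambda r: r.subject_id)
    if not cases or not controls:
        return MatchResult(
            (), tuple(c.subject_id for c in cases), tuple(c.subject_id for c in controls)
        )

    rows, cols = [], []
    for i, case in enumerate(cases):
        for j, ctl in enumerate(controls):
            if _match_compatible(case, ctl, bmi_tol, age_tol):
                rows.append(i)
                cols.append(j)
    graph = csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(cases), len(controls)),
    )
    # perm[j] = index of the case matched to control j, -1 if unmatched
    perm = maximum_bipartite_matching(graph, perm_type="row")
    pairs = []
    for j, i in enumerate(perm):
        if i >= 0:
            pairs.append((cases[i].subject_id, controls[j].subject_id))
    matched_cases = {c for c, _ in pairs}
    matched_controls = {c for _, c in pairs}
    return MatchResult(
        pairs=tuple(sorted(pairs)),
        unmatched_cases=tuple(
            c.subject_id for c in cases if c.subject_id not in matched_cases
        ),
        unmatched_controls=tuple(
            c.subject_id for c in controls if c.subject_id not in matched_controls
        ),
    )


@dataclass(frozen=True)
class SplitPlan:
    """Subject-level nested cross-validation assignment.

    Each subject carries one outer fold index (0..outer-1) and one inner
    index (0..inner-1).  For outer fold ``o`` and inner index ``i``:
    test = subjects with outer == o; validation = subjects with outer != o
    and inner == i; training = the rest.  This yields ``outer * inner``
    (train, val, test) assignments, with every inner split partitioning the
    outer-training pool.
    """

    frame: pd.DataFrame  # columns: subject_id, outer_fold, inner_fold
    outer: int
    inner: int
    seed: int

    def assignments(self):
        """Yield ``(outer, inner, train_ids, val_ids, test_ids)`` tuples."""
        df = self.frame
        for o in range(self.outer):
            test = df.loc[df.outer_fold == o, "subject_id"]
            pool = df[df.outer_fold != o]
            for i in range(self.inner):
                val = pool.loc[pool.inner_fold == i, "subject_id"]
                train = pool.loc[pool.inner_fold != i, "subject_id"]
                yield o, i, tuple(train), tuple(val), tuple(test)


def make_nested_splits(subject_ids, is_case, outer=7, inner=6, seed=0) -> SplitPlan:
    """Stratified subject-level nested split plan.

    Within each stratum (case / control) subjects are shuffled and dealt
    round-robin into the outer folds, then dealt again into inner indices
    within each (stratum, outer fold) cell, so both levels stay balanced.
    Deterministic given ``seed``.
    """
    subject_ids = np.asarray(subject_ids)
    is_case = np.asarray(is_case, dtype=bool)
    if subject_ids.shape != is_case.shape:
        raise ValueError("subject_ids and is_case must align")
    if len(set(subject_ids.tolist())) != len(subject_ids):
        raise ValueError("subject_ids must be unique")
    rng = np.random.default_rng([seed, 211])
    rows = []
    for stratum in (False, True):
        ids = np.sort(subject_ids[is_case == stratum])
        if len(ids) < outer:
            raise ValueError(
                f"stratum {'case' if stratum else 'control'} has {len(ids)} "
                f"subjects; need at least {outer}"
            )
        ids = ids[rng.permutation(len(ids))]
        outer_fold = np.arange(len(ids)) % outer
        for o in range(outer):
            cell = ids[outer_fold == o]
            cell = cell[rng.permutation(len(cell))]
            for pos, sid in enumerate(cell):
                rows.append(
                    {"subject_id": sid, "outer_fold": o, "inner_fold": pos % inner}
                )
    frame = (
        pd.DataFrame(rows, columns=["subject_id", "outer_fold", "inner_fold"])
        .sort_values("subject_id")
        .reset_index(drop=True)
    )
    return SplitPlan(frame=frame, outer=outer, inner=inner, seed=seed)
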