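"""Domain types and time-indexing utilities.

A study couples, per subject, a sparse longitudinal biomarker record with a
right-censored event time and (optionally) the time ``rho`` of a single
intermediate event (a reoperation, a serious adverse event, ...) that changes
both the biomarker trajectory and the instantaneous risk from ``rho`` onwards.
All times are anchored at study entry (t = 0 at baseline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "EventClock",
    "SubjectData",
    "StudyData",
    "ValidationReport",
    "event_indicator",
    "relative_time",
    "validate_study",
    "read_study",
    "write_study",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EventClock:
    """Clock of a single intermediate event at time ``rho`` (``None`` = never).

    Exposes the binary status process R(t) = I(t >= rho) and the post-event
    time t+ = max(0, t - rho).  The status is closed at ``rho``: R(rho) = 1,
    so a record taken exactly at the event belongs to the post-event regime.
    """

    rho: float | None = None

    def __post_init__(self) -> None:
        if self.rho is not None and self.rho < 0:
            raise ValueError(f"intermediate-event time must be >= 0, got {self.rho}")

    def indicator(self, t):
        return event_indicator(self, t)

    def relative_time(self, t):
        return relative_time(self, t)


def _check_nonnegative_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    return t


def event_indicator(clock: EventClock, t):
    """R(t) = I(t >= rho); identically 0 when no intermediate event occurred."""
    t = _check_nonnegative_time(t)
    if clock.rho is None:
        out = np.zeros_like(t)
    else:
        out = (t >= clock.rho).astype(float)
    return out if out.ndim else float(out)


def relative_time(clock: EventClock, t):
    """t+ = max(0, t - rho); identically 0 when no intermediate event occurred."""
    t = _check_nonnegative_time(t)
    if clock.rho is None:
        out = np.zeros_like(t)
    else:
        out = np.maximum(0.0, t - clock.rho)
    return out if out.ndim else float(out)


@dataclass
class SubjectData:
    """One subject: longitudinal record + survival triple + intermediate event.

    Parameters
    ----------
    id : hashable identifier.
    obs_times : strictly increasing visit times, all <= ``T_obs``.
    y : biomarker values aligned with ``obs_times``.
    T_obs : observed event or censoring time (> 0).
    delta : event indicator, 1 = event observed, 0 = censored.
    rho : intermediate-event time, or ``None`` if it never occurred.
    x_baseline : baseline covariates entering the longitudinal submodel.
    w_baseline : baseline covariates entering the survival submodel.
    """

    id: object
    obs_times: np.ndarray
    y: np.ndarray
    T_obs: float
    delta: int
    rho: float | None = None
    x_baseline: np.ndarray = field(default_factory=lambda: np.zeros(0))
    w_baseline: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.obs_times = np.atleast_1d(np.asarray(self.obs_times, dtype=float))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        self.x_baseline = np.atleast_1d(np.asarray(self.x_baseline, dtype=float))
        self.w_baseline = np.atleast_1d(np.asarray(self.w_baseline, dtype=float))
        if self.rho is not None and np.isnan(self.rho):
            self.rho = None
        # rows with missing biomarker values carry no information for a
        # Gaussian measurement model: drop them rather than guess
        keep = np.isfinite(self.y)
        if not keep.all():
            logger.warning(
                "subject %s: dropping %d visit(s) with missing biomarker values",
                self.id,
                int((~keep).sum()),
            )
            self.obs_times = self.obs_times[keep]
            self.y = self.y[keep]

    @property
    def clock(self) -> EventClock:
        return EventClock(self.rho)

    @property
    def n_obs(self) -> int:
        return self.obs_times.size

    def violations(self) -> list[str]:
        out = []
        if self.obs_times.size != self.y.size:
            out.append(f"subject {self.id}: obs_times and y lengths differ")
        if not self.T_obs > 0:
            out.append(f"subject {self.id}: T_obs must be > 0, got {self.T_obs}")
        if self.delta not in (0, 1):
            out.append(f"subject {self.id}: delta must be 0 or 1, got {self.delta}")
        if self.obs_times.size:
            if np.any(np.diff(self.obs_times) <= 0):
                out.append(f"subject {self.id}: obs_times not strictly increasing")
            if np.any(self.obs_times < 0):
                out.append(f"subject {self.id}: negative visit time")
            if np.any(self.obs_times > self.T_obs + 1e-12):
                out.append(f"subject {self.id}: visit time after T_obs")
        if self.rho is not None and self.rho < 0:
            out.append(f"subject {self.id}: negative intermediate-event time")
        return out


@dataclass
class StudyData:
    """A sample of subjects plus column metadata (names and units)."""

    subjects: list[SubjectData]
    meta: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def ids(self) -> list:
        return [s.id for s in self.subjects]

    def subset(self, ids) -> "StudyData":
        ids = set(ids)
        return StudyData(
            subjects=[replace(s) for s in self.subjects if s.id in ids],
            meta=dict(self.meta),
        )

    def survival_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids(),
                "time_obs": [s.T_obs for s in self.subjects],
                "status": [s.delta for s in self.subjects],
                "rho": [np.nan if s.rho is None else s.rho for s in self.subjects],
            }
        )


@dataclass
class ValidationReport:
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok


def validate_study(data: StudyData) -> ValidationReport:
    """Collect all invariant violations; passes iff the list is empty."""
    violations: list[str] = []
    if not data.subjects:
        violations.append("study has no subjects")
    ids = data.ids()
    if len(set(ids)) != len(ids):
        violations.append("subject ids are not unique")
    for s in data.subjects:
        violations.extend(s.violations())
    return ValidationReport(violations)


# ---------------------------------------------------------------------------
# CSV interchange.  Long-format longitudinal table: id, time, y [, covariates];
# subject-level survival table: id, time_obs, status, rho [, covariates], with
# an empty rho field meaning "no intermediate event".
# ---------------------------------------------------------------------------


def read_study(
    longitudinal_csv,
    survival_csv,
    x_covariates: list[str] | None = None,
    w_covariates: list[str] | None = None,
) -> StudyData:
    long_df = pd.read_csv(longitudinal_csv, float_precision="round_trip")
    surv_df = pd.read_csv(survival_csv, float_precision="round_trip")
    for col in ("id", "time", "y"):
        if col not in long_df.columns:
            raise ValueError(f"longitudinal table is missing column {col!r}")
    for col in ("id", "time_obs", "status"):
        if col not in surv_df.columns:
            raise ValueError(f"survival table is missing column {col!r}")
    x_covariates = list(x_covariates or [])
    w_covariates = list(w_covariates or [])
    subjects = []
    grouped = dict(iter(long_df.groupby("id", sort=False)))
    for row in surv_df.itertuples(index=False):
        rec = grouped.get(row.id)
        times = rec["time"].to_numpy(float) if rec is not None else np.zeros(0)
        yvals = rec["y"].to_numpy(float) if rec is not None else np.zeros(0)
        order = np.argsort(times, kind="stable")
        rho = getattr(row, "rho", np.nan)
        subjects.append(
            SubjectData(
                id=row.id,
                obs_times=times[order],
                y=yvals[order],
                T_obs=float(row.time_obs),
                delta=int(row.status),
                rho=None if pd.isna(rho) else float(rho),
                x_baseline=np.array([getattr(row, c) for c in x_covariates], float),
                w_baseline=np.array([getattr(row, c) for c in w_covariates], float),
            )
        )
    meta = {"x_covariates": x_covariates, "w_covariates": w_covariates}
    return StudyData(subjects=subjects, meta=meta)


def write_study(data: StudyData, longitudinal_csv, survival_csv) -> None:
    x_names = data.meta.get("x_covariates", [])
    w_names = data.meta.get("w_covariates", [])
    long_rows, surv_rows = [], []
    for s in data.subjects:
        for t, y in zip(s.obs_times, s.y):
            long_rows.append({"id": s.id, "time": t, "y": y})
        row = {
            "id": s.id,
            "time_obs": s.T_obs,
            "status": s.delta,
            "rho": np.nan if s.rho is None else s.rho,
        }
        row.update({name: v for name, v in zip(x_names, s.x_baseline)})
        row.update({name: v for name, v in zip(w_names, s.w_baseline)})
        surv_rows.append(row)
    # %.17g round-trips IEEE doubles bit-exactly through the CSV
    pd.DataFrame(long_rows).to_csv(longitudinal_csv, index=False,
                                   float_format="%.17g")
    pd.DataFrame(surv_rows).to_csv(survival_csv, index=False,
                                   float_format="%.17g")
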