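"""Wide-format discrete-time survival data.

One row per subject. Follow-up is divided into K intervals t = 1..K; within
interval t the censoring indicator C_t precedes the event indicator Y_t, so a
subject censored in interval t has a missing event status from t onward. Both
processes are absorbing: once Y_t = 1 the subject keeps Y = 1, and once
C_t = 1 the subject stays censored. Missing entries are stored as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WideSurvivalData",
    "DiscretizationSpec",
    "Violation",
    "discretize_followup",
    "validate",
    "read_wide_csv",
    "write_wide_csv",
]


@dataclass
class WideSurvivalData:
    """Subject-level wide table for a point exposure and a discretized outcome.

    Parameters
    ----------
    baseline : pandas.DataFrame
        Baseline covariates (L1), one row per subject. Numeric columns;
        categorical covariates should be coded numerically by the caller.
    exposure : numpy.ndarray
        Integer exposure codes in {0, ..., m-1}, one per subject.
    censor : numpy.ndarray of shape (n, K)
        Censoring indicators C_1..C_K with entries in {0, 1, NaN}.
    event : numpy.ndarray of shape (n, K)
        Event indicators Y_1..Y_K with entries in {0, 1, NaN}; missing from
        the first censored interval onward.
    tv_covariates : dict[int, pandas.DataFrame], optional
        Time-varying covariate blocks L_t for t >= 2, keyed by interval.
    """

    baseline: pd.DataFrame
    exposure: np.ndarray
    censor: np.ndarray
    event: np.ndarray
    tv_covariates: dict[int, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.exposure = np.asarray(self.exposure)
        self.censor = np.asarray(self.censor, dtype=float)
        self.event = np.asarray(self.event, dtype=float)
        if self.censor.shape != self.event.shape:
            raise ValueError("censor and event matrices must share a shape")
        if len(self.baseline) != self.censor.shape[0]:
            raise ValueError("baseline covariates and matrices disagree on n")

    @property
    def n(self) -> int:
        return self.censor.shape[0]

    @property
    def K(self) -> int:
        return self.censor.shape[1]

    @property
    def exposure_levels(self) -> np.ndarray:
        return np.unique(self.exposure)

    def event_before(self, t: int) -> np.ndarray:
        """Boolean mask Y_{t-1} = 1, with Y_0 identically 0."""
        if t <= 1:
            return np.zeros(self.n, dtype=bool)
        return self.event[:, t - 2] == 1

    def uncensored_through(self, t: int) -> np.ndarray:
        """Boolean mask C_t = 0, with C_0 identically 0."""
        if t <= 0:
            return np.ones(self.n, dtype=bool)
        return self.censor[:, t - 1] == 0

    def risk_set(self, t: int) -> np.ndarray:
        """Subjects uncensored at t and event-free through t-1."""
        return self.uncensored_through(t) & ~self.event_before(t)


@dataclass(frozen=True)
class DiscretizationSpec:
    """Half-open interval grid (b_{j-1}, b_j] with b_0 = 0 < b_1 < ... < b_K."""

    boundaries: tuple[float, ...]

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.size < 1:
            raise ValueError("at least one interval boundary is required")
        if np.any(b <= np.concatenate([[0.0], b[:-1]])):
            raise ValueError("boundaries must be strictly increasing and positive")

    @property
    def K(self) -> int:
        return len(self.boundaries)


@dataclass(frozen=True)
class Violation:
    rule: str
    subject: int
    interval: int


def discretize_followup(
    followup_time: np.ndarray,
    event_indicator: np.ndarray,
    spec: DiscretizationSpec,
    baseline: pd.DataFrame | None = None,
    exposure: np.ndarray | None = None,
    administrative_censor_at_end: bool = False,
) -> WideSurvivalData:
    """Map continuous follow-up to censor/event indicator matrices.

    A subject whose follow-up ends in interval j with the event gets
    Y_j..Y_K = 1 and is never censored; one whose follow-up ends by censoring
    gets C_j..C_K = 1 with Y missing from j on. Subjects whose event-free
    follow-up reaches the last boundary are coded as complete (no censoring
    record) unless ``administrative_censor_at_end`` is set, in which case
    they receive C_K = 1.
    """
    times = np.asarray(followup_time, dtype=float)
    events = np.asarray(event_indicator)
    if times.shape != events.shape:
        raise ValueError("followup_time and event_indicator must align")
    if np.any(times < 0):
        raise ValueError("negative follow-up times")
    b = np.asarray(spec.boundaries, dtype=float)
    if np.any(times > b[-1]):
        raise ValueError("follow-up time exceeds the last interval boundary")
    n, K = times.size, spec.K
    censor = np.zeros((n, K))
    event = np.zeros((n, K))
    # half-open (b_{j-1}, b_j]: a time equal to b_j belongs to interval j
    interval = np.searchsorted(b, times, side="left") + 1
    interval = np.clip(interval, 1, K)
    for i in range(n):
        j = interval[i]
        if events[i] == 1:
            event[i, j - 1 :] = 1.0
        elif times[i] >= b[-1] and not administrative_censor_at_end:
            continue  # complete event-free follow-up
        else:
            censor[i, j - 1 :] = 1.0
            event[i, j - 1 :] = np.nan
    if baseline is None:
        baseline = pd.DataFrame(index=range(n))
    if exposure is None:
        exposure = np.zeros(n, dtype=int)
    return WideSurvivalData(baseline=baseline, exposure=exposure, censor=censor, event=event)


def _is_indicator(x: float) -> bool:
    return np.isnan(x) or x in (0.0, 1.0)


def validate(data: WideSurvivalData) -> list[Violation]:
    """Check the wide-format invariants row by row.

    Returns an empty list iff the data satisfy: entries of both matrices in
    {0, 1, missing}; the event process is absorbing; the censoring process is
    absorbing (and never missing once censored); and event indicators are
    missing from the first censored interval onward.
    """
    out: list[Violation] = []
    n, K = data.n, data.K
    for i in range(n):
        censored = False
        had_event = False
        for t in range(1, K + 1):
            c = data.censor[i, t - 1]
            y = data.event[i, t - 1]
            if not _is_indicator(c) or not _is_indicator(y):
                out.append(Violation("domain", i, t))
                continue
            if censored and c != 1.0:
                out.append(Violation("absorbing-censoring", i, t))
            if had_event and not np.isnan(y) and y != 1.0:
                out.append(Violation("absorbing-event", i, t))
            if (censored or c == 1.0) and not np.isnan(y):
                out.append(Violation("missing-after-censoring", i, t))
            censored = censored or c == 1.0
            had_event = had_event or y == 1.0
    return out


def _column_block(prefix: str, K: int) -> list[str]:
    return [f"{prefix}{t}" for t in range(1, K + 1)]


def write_wide_csv(
    data: WideSurvivalData,
    path,
    Avar: str = "A",
    Yvar: list[str] | None = None,
    Cvar: list[str] | None = None,
) -> None:
    """Write one row per subject; missing cells become empty strings."""
    Yvar = Yvar or _column_block("Y", data.K)
    Cvar = Cvar or _column_block("C", data.K)
    df = data.baseline.reset_index(drop=True).copy()
    df[Avar] = data.exposure
    for t in range(1, data.K + 1):
        df[Cvar[t - 1]] = data.censor[:, t - 1]
        df[Yvar[t - 1]] = data.event[:, t - 1]
    for t, block in data.tv_covariates.items():
        for col in block.columns:
            df[col] = block[col].to_numpy()
    df.to_csv(path, index=False)


def read_wide_csv(
    path,
    Yvar: list[str],
    Cvar: list[str],
    Avar: str,
    L0var: list[str],
    Lvar: dict[int, list[str]] | None = None,
) -> WideSurvivalData:
    """Read a wide CSV given explicit column mappings.

    ``Yvar``/``Cvar`` list the per-interval outcome and censoring columns in
    time order; ``L0var`` the baseline covariates; ``Lvar`` optionally maps
    interval t >= 2 to its time-varying covariate columns. Empty cells and NA
    tokens are read as missing.
    """
    if len(Yvar) != len(Cvar):
        raise ValueError("Yvar and Cvar must have equal length K")
    df = pd.read_csv(path)
    missing_cols = [c for c in [*Yvar, *Cvar, Avar, *L0var] if c not in df.columns]
    if missing_cols:
        raise ValueError(f"columns not found in {path}: {missing_cols}")
    tv = {}
    if Lvar:
        for t, cols in Lvar.items():
            absent = [c for c in cols if c not in df.columns]
            if absent:
                raise ValueError(f"columns not found in {path}: {absent}")
            tv[int(t)] = df[cols].copy()
    return WideSurvivalData(
        baseline=df[L0var].copy(),
        exposure=df[Avar].to_numpy(dtype=int),
        censor=df[Cvar].to_numpy(dtype=float),
        event=df[Yvar].to_numpy(dtype=float),
        tv_covariates=tv,
    )
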