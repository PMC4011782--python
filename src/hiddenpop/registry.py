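"""Register data: event tables and their reduction to sufficient statistics.

A register is a long-format table of timestamped registration events (one
row per care occasion, arrest, prescription fill, ...).  Two reductions of
such a table carry all the information the population-size estimators use:

* :class:`EpochCounts` -- the number of *previously unregistered* persons
  first appearing in each of ``M`` equal-duration epochs (``n_1..n_M``).
  This is the sufficient statistic for the removal maximum-likelihood
  estimator.
* :class:`CaptureHistogram` -- the number of persons registered exactly
  ``j`` times (``h_j``), the sufficient statistic for truncated-Poisson
  estimators (Chao, Zelterman).

Time is a 0-based discrete index; all intervals are half-open
``[start, end)``.  Calendar dates are converted to day indices at load
time, so everything downstream is calendar-agnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "EventTable",
    "EpochCounts",
    "CaptureHistogram",
    "load_events",
    "epoch_counts",
    "capture_histogram",
    "split_window",
]


@dataclass(frozen=True)
class EventTable:
    """Validated registration events over a discrete observation window.

    Parameters
    ----------
    events : pandas.DataFrame
        Columns ``person_id`` (str) and ``time`` (int); one row per
        distinct (person, time-step) registration.  Duplicate rows at the
        same (person, time) have already been collapsed.
    T : int
        Window length: every time index lies in ``[0, T)``.
    """

    events: pd.DataFrame
    T: int

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ParameterError(f"window length T must be positive, got {self.T}")
        ev = self.events
        for col in ("person_id", "time"):
            if col not in ev.columns:
                raise InputError(f"event table lacks required column {col!r}")
        if len(ev):
            t = ev["time"].to_numpy()
            if t.min() < 0:
                raise InputError("negative time index in event table")
            if t.max() >= self.T:
                raise InputError(
                    f"time index {t.max()} outside window [0, {self.T})"
                )

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_persons(self) -> int:
        """Number of distinct persons with at least one event."""
        return self.events["person_id"].nunique()

    def first_times(self) -> pd.Series:
        """Time of first registration, indexed by person_id."""
        return self.events.groupby("person_id", sort=True)["time"].min()

    def event_counts(self) -> pd.Series:
        """Number of registrations per person, indexed by person_id."""
        return self.events.groupby("person_id", sort=True)["time"].size()

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False)


@dataclass(frozen=True)
class EpochCounts:
    """First-registration counts ``n_1..n_M`` over M equal epochs.

    ``counts[j-1]`` is the number of persons whose first retained
    registration falls in epoch ``j``; each person contributes to exactly
    one epoch.  ``d`` is the epoch duration in time-steps (metadata only:
    the estimators work on the per-epoch scale).
    """

    counts: tuple
    d: int = 1

    def __post_init__(self) -> None:
        c = tuple(int(x) for x in self.counts)
        object.__setattr__(self, "counts", c)
        if len(c) < 1:
            raise ParameterError("EpochCounts needs at least one epoch")
        if any(x < 0 for x in c):
            raise ParameterError("epoch counts must be non-negative")
        if self.d < 1:
            raise ParameterError("epoch duration d must be positive")

    @property
    def M(self) -> int:
        return len(self.counts)

    @property
    def s(self) -> int:
        """Total number of distinct persons observed, ``s_M``."""
        return sum(self.counts)

    @property
    def removals_weighted(self) -> int:
        """``X = sum_j (j-1) n_j``, the removal statistic of the counts."""
        return sum(j * n for j, n in enumerate(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch": np.arange(1, self.M + 1), "n": self.counts, "d": self.d}
        )


@dataclass(frozen=True)
class CaptureHistogram:
    """Counts ``h_j`` of persons registered exactly ``j`` times (j >= 1).

    The zero bin ``h_0`` (never-registered persons) is by definition
    unobservable; estimating it is the whole point.

    ``observed_total`` defaults to ``sum(h_j)`` and can be passed
    explicitly when only the low-order frequencies of a published table
    are known.  Counts may be non-integral: plugging *expected*
    frequencies ``E(h_j)`` into the estimators is a standard analytic
    check.
    """

    h: dict
    observed_total: float | None = None

    def __post_init__(self) -> None:
        hh = {}
        for j, c in self.h.items():
            c = float(c)
            if c == 0:
                continue
            hh[int(j)] = int(c) if c.is_integer() else c
        if any(j < 1 for j in hh):
            raise ParameterError("capture counts j must be >= 1 (h_0 is hidden)")
        if any(c < 0 for c in hh.values()):
            raise ParameterError("histogram counts must be non-negative")
        object.__setattr__(self, "h", hh)
        total = sum(hh.values())
        if self.observed_total is None:
            object.__setattr__(self, "observed_total", total)
        elif self.observed_total < total:
            raise ParameterError(
                f"observed_total={self.observed_total} below sum of h_j={total}"
            )

    def __getitem__(self, j: int) -> int:
        return self.h.get(int(j), 0)

    @property
    def n_events(self) -> int:
        """Total registrations accounted for by the histogram, sum_j j*h_j."""
        return sum(j * c for j, c in self.h.items())

    def to_frame(self) -> pd.DataFrame:
        js = sorted(self.h)
        return pd.DataFrame({"j": js, "h": [self.h[j] for j in js]})


def load_events(
    path,
    id_col: str = "person_id",
    time_col: str = "time",
    T: int | None = None,
    date_origin: str | None = None,
    sep: str | None = None,
) -> EventTable:
    """Read an event table from delimited text.

    Parameters
    ----------
    path : str or path-like
        CSV/TSV file with a header row.
    id_col, time_col : str
        Names of the person-identifier and time columns.
    T : int, optional
        Window length.  Defaults to ``max(time) + 1``.
    date_origin : str, optional
        If given, the time column holds ISO-8601 dates which are converted
        to day indices relative to this origin date (origin itself is
        day 0).  Otherwise the column must hold non-negative integers.
    sep : str, optional
        Field separator; inferred from the file when omitted.

    Returns
    -------
    EventTable
        Validated table with duplicate (person, time) rows collapsed.
    """
    try:
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read event file {path}: {exc}") from exc
    for col in (id_col, time_col):
        if col not in df.columns:
            raise InputError(
                f"column {col!r} not found in {path} (have: {list(df.columns)})"
            )
    out = pd.DataFrame(
        {"person_id": df[id_col].astype(str), "time": df[time_col]}
    )
    if date_origin is not None:
        origin = pd.Timestamp(date_origin)
        try:
            dates = pd.to_datetime(out["time"], format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise InputError(f"unparseable date in column {time_col!r}: {exc}") from exc
        out["time"] = (dates - origin).dt.days
    else:
        times = pd.to_numeric(out["time"], errors="coerce")
        bad = times.isna() | (times != times.round())
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise InputError(
                f"unparseable integer time at data row {row} of {path}: "
                f"{out['time'].iloc[row]!r}"
            )
        out["time"] = times.astype(int)
    if len(out) and out["time"].min() < 0:
        row = int(out["time"].idxmin())
        raise InputError(f"negative time index at data row {row} of {path}")

    n_raw = len(out)
    out = out.drop_duplicates(["person_id", "time"], ignore_index=True)
    n_dup = n_raw - len(out)
    if n_dup:
        logger.info("collapsed %d duplicate (person, time) rows", n_dup)

    if T is None:
        T = int(out["time"].max()) + 1 if len(out) else 1
    return EventTable(events=out, T=int(T))


def _retained(events: EventTable, burn_in: int) -> pd.DataFrame:
    """Drop the burn-in prefix and every person whose FIRST event is in it.

    A first registration inside the burn-in may be the continuation of an
    unobserved earlier care sequence, so such persons are excluded
    entirely, not merely truncated.
    """
    if burn_in < 0:
        raise ParameterError("burn_in must be non-negative")
    if burn_in == 0:
        return events.events
    ev = events.events
    first = ev.groupby("person_id")["time"].transform("min")
    return ev[(first >= burn_in)]


def epoch_counts(events: EventTable, M: int, burn_in: int = 0) -> EpochCounts:
    """Reduce an event table to first-registration counts over M epochs.

    The post-burn-in window ``[burn_in, T)`` of length ``T' = T - burn_in``
    is split into M half-open epochs of equal duration ``d = T' // M``;
    trailing time-steps beyond ``burn_in + M*d`` are discarded (with a
    logged warning) so that all epochs have equal length.  Each person
    contributes once, to the epoch containing their first retained event.
    """
    if M < 2:
        raise ParameterError(f"need at least M=2 epochs, got M={M}")
    T_eff = events.T - burn_in
    if T_eff < M:
        raise ParameterError(
            f"window of length {T_eff} after burn-in cannot hold {M} epochs"
        )
    d = T_eff // M
    end = burn_in + M * d
    if end < events.T:
        logger.warning(
            "discarding %d trailing time-steps [%d, %d) not filling an epoch",
            events.T - end, end, events.T,
        )
    ev = _retained(events, burn_in)
    first = ev.groupby("person_id")["time"].min()
    first = first[first < end]  # persons first seen in the dropped tail contribute nothing
    idx = (first.to_numpy() - burn_in) // d
    counts = np.bincount(idx, minlength=M)
    return EpochCounts(counts=tuple(int(c) for c in counts), d=d)


def capture_histogram(events: EventTable, burn_in: int = 0) -> CaptureHistogram:
    """Reduce an event table to counts of persons seen exactly j times.

    Uses the window ``[burn_in, T)``; persons whose first event falls in
    the burn-in are excluded entirely (same rule as :func:`epoch_counts`).
    """
    ev = _retained(events, burn_in)
    per_person = ev.groupby("person_id")["time"].size()
    if len(per_person) == 0:
        return CaptureHistogram(h={})
    j, c = np.unique(per_person.to_numpy(), return_counts=True)
    return CaptureHistogram(h=dict(zip(j.tolist(), c.tolist())))


def split_window(events: EventTable, fraction: float) -> tuple[EventTable, EventTable]:
    """Split the window for the Chao stability diagnostic.

    Returns ``(head, full)`` where ``head`` covers ``[0, floor(T*fraction))``
    and ``full`` is the original table.  Under the Poisson assumption the
    Chao estimate from the head should agree with the full-window estimate
    up to sampling error; a strong dependence on the window flags a
    violated assumption.
    """
    if not (0.0 < fraction < 1.0):
        raise ParameterError(f"fraction must be in (0, 1), got {fraction}")
    T_head = int(np.floor(events.T * fraction))
    if T_head < 1:
        raise ParameterError(
            f"fraction {fraction} leaves an empty head window for T={events.T}"
        )
    head = events.events[events.events["time"] < T_head].reset_index(drop=True)
    return EventTable(events=head, T=T_head), events
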