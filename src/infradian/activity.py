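"""Locomotor-activity traces and their summary statistics.

Time conventions
----------------
Absolute time is measured in hours from an arbitrary origin chosen so that
zeitgeber time is ``t % 24``: ZT0 (lights on) at multiples of 24 h, ZT12
(lights off) halfway through each day.  Blood sampling happens at ZT6, so
``sampling_time % 24 == 6``.

Two derived quantities are the prediction targets downstream:

* the 24 h LA — distance traveled between ZT0 of the day before sampling
  and ZT0 of the sampling day (an interval that ends 6 h *before* the
  sampling instant);
* the 3 h LAs — the 24 consecutive 3 h windows tiling the 72 h before the
  sampling instant, window ``w`` covering ``[3(w-1), 3w)`` hours before
  sampling, each annotated light or dark by its ZT span.

All intervals are half-open ``[start, end)`` so that no bin is ever counted
twice.  Bins coarser than 3 h are rejected rather than interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._io import read_table, write_table
from .exceptions import MissingDataError, ParseError

LIGHTS_ON_ZT = 0.0
LIGHTS_OFF_ZT = 12.0

N_WINDOWS = 24
WINDOW_HOURS = 3.0
LOOKBACK_HOURS = 72.0

_EPS = 1e-9


@dataclass
class ActivityTrace:
    """One mouse's distance-per-bin time series, ZT-aligned.

    Parameters
    ----------
    mouse_id : str
        Animal identifier.
    bin_starts : ndarray
        Start of each bin in absolute hours (``ZT = t % 24``); must be
        contiguous and uniformly spaced by ``bin_hours``.
    distances : ndarray
        Distance traveled in each bin, cm, nonnegative.
    bin_hours : float
        Bin width in hours; must divide 24.
    sampling_time : float
        Absolute time of blood sampling, at ZT6, strictly inside the trace.
    """

    mouse_id: str
    bin_starts: np.ndarray
    distances: np.ndarray
    bin_hours: float
    sampling_time: float

    def __post_init__(self) -> None:
        self.bin_starts = np.asarray(self.bin_starts, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.bin_starts.ndim != 1 or self.bin_starts.shape != self.distances.shape:
            raise ParseError(f"{self.mouse_id}: bin_starts and distances must be 1-D and equal length")
        if len(self.bin_starts) == 0:
            raise ParseError(f"{self.mouse_id}: empty trace")
        if self.bin_hours <= 0 or abs(24.0 / self.bin_hours - round(24.0 / self.bin_hours)) > _EPS:
            raise ParseError(f"{self.mouse_id}: bin_hours={self.bin_hours} must divide 24")
        steps = np.diff(self.bin_starts)
        if len(steps) and not np.allclose(steps, self.bin_hours, atol=_EPS):
            raise ParseError(f"{self.mouse_id}: bins are not contiguous with uniform width {self.bin_hours}")
        if np.any(self.distances < 0):
            raise ParseError(f"{self.mouse_id}: negative distances")
        if not (self.start < self.sampling_time < self.end):
            raise MissingDataError(
                f"{self.mouse_id}: sampling_time {self.sampling_time} outside trace [{self.start}, {self.end})"
            )
        if abs((self.sampling_time % 24.0) - 6.0) > _EPS:
            raise ParseError(f"{self.mouse_id}: sampling_time must fall at ZT6, got ZT{self.sampling_time % 24.0:g}")

    @property
    def start(self) -> float:
        return float(self.bin_starts[0])

    @property
    def end(self) -> float:
        return float(self.bin_starts[-1] + self.bin_hours)

    @property
    def duration_days(self) -> float:
        return (self.end - self.start) / 24.0

    def interval_distance(self, t0: float, t1: float) -> float:
        """Total distance over the half-open absolute interval ``[t0, t1)``.

        Interval endpoints must align with bin edges and be fully covered by
        the trace; otherwise a :class:`MissingDataError` names the gap.
        """
        if t1 <= t0:
            raise ValueError("empty or inverted interval")
        if t0 < self.start - _EPS or t1 > self.end + _EPS:
            raise MissingDataError(
                f"{self.mouse_id}: interval [{t0:g}, {t1:g}) not covered by trace [{self.start:g}, {self.end:g})"
            )
        i0 = (t0 - self.start) / self.bin_hours
        i1 = (t1 - self.start) / self.bin_hours
        if abs(i0 - round(i0)) > 1e-6 or abs(i1 - round(i1)) > 1e-6:
            raise MissingDataError(
                f"{self.mouse_id}: interval [{t0:g}, {t1:g}) does not align with {self.bin_hours} h bin edges"
            )
        return float(self.distances[int(round(i0)) : int(round(i1))].sum())


def _window_annotation(zt_start: float, width: float) -> str:
    """Light/dark label for a window spanning ``[zt_start, zt_start+width)`` in ZT."""
    zt_start = zt_start % 24.0
    zt_end = zt_start + width
    if zt_start >= LIGHTS_ON_ZT and zt_end <= LIGHTS_OFF_ZT + _EPS:
        return "light"
    if zt_start >= LIGHTS_OFF_ZT - _EPS and zt_end <= 24.0 + _EPS:
        return "dark"
    return "split"


def la_24h(trace: ActivityTrace) -> float:
    """Distance traveled between ZT0 of the day before sampling and ZT0 of
    the sampling day (cm).

    With sampling at ZT6 this is the absolute interval
    ``[sampling_time - 30, sampling_time - 6)``.
    """
    zt0_sampling_day = trace.sampling_time - 6.0
    return trace.interval_distance(zt0_sampling_day - 24.0, zt0_sampling_day)


def la_3h_windows(trace: ActivityTrace) -> pd.DataFrame:
    """The 24 labeled 3 h-window distances before the sampling instant.

    Returns a frame indexed by window number 1..24 with columns
    ``hours_before_start`` (= 3(w-1)), ``hours_before_end`` (= 3w),
    ``distance`` (cm) and ``phase`` (light/dark/split annotation of the
    window's ZT span).  Window ``w`` covers absolute
    ``[sampling_time - 3w, sampling_time - 3(w-1))``.
    """
    if trace.bin_hours > WINDOW_HOURS + _EPS:
        raise ParseError(
            f"{trace.mouse_id}: bins of {trace.bin_hours} h are coarser than the {WINDOW_HOURS:g} h window"
        )
    s = trace.sampling_time
    rows = []
    for w in range(1, N_WINDOWS + 1):
        t0 = s - WINDOW_HOURS * w
        t1 = s - WINDOW_HOURS * (w - 1)
        rows.append(
            {
                "hours_before_start": WINDOW_HOURS * (w - 1),
                "hours_before_end": WINDOW_HOURS * w,
                "distance": trace.interval_distance(t0, t1),
                "phase": _window_annotation(t0 % 24.0, WINDOW_HOURS),
            }
        )
    return pd.DataFrame(rows, index=pd.RangeIndex(1, N_WINDOWS + 1, name="window"))


@dataclass
class ActivitySummary:
    """Derived prediction targets for one mouse: the 24 h LA scalar and the
    24 labeled 3 h-window LAs."""

    mouse_id: str
    la_24h: float
    la_3h: pd.DataFrame = field(repr=False)

    @classmethod
    def from_trace(cls, trace: ActivityTrace) -> "ActivitySummary":
        return cls(mouse_id=trace.mouse_id, la_24h=la_24h(trace), la_3h=la_3h_windows(trace))


def summarize_traces(traces: Iterable[ActivityTrace]) -> list[ActivitySummary]:
    return [ActivitySummary.from_trace(t) for t in traces]


def summaries_to_frame(summaries: Sequence[ActivitySummary]) -> pd.DataFrame:
    """One row per mouse: ``la_24h``, ``la_3h_w1`` .. ``la_3h_w24``."""
    rows = {}
    for s in summaries:
        row = {"la_24h": s.la_24h}
        for w in s.la_3h.index:
            row[f"la_3h_w{w}"] = s.la_3h.loc[w, "distance"]
        rows[s.mouse_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "mouse_id"
    return df


def window_targets(summaries: Sequence[ActivitySummary], window: int) -> pd.Series:
    """Per-mouse 3 h LA for one window (1..24), indexed by mouse_id."""
    if not 1 <= window <= N_WINDOWS:
        raise ValueError(f"window must be in 1..{N_WINDOWS}")
    return pd.Series(
        {s.mouse_id: s.la_3h.loc[window, "distance"] for s in summaries}, name=f"la_3h_w{window}"
    )


def la24h_targets(summaries: Sequence[ActivitySummary]) -> pd.Series:
    return pd.Series({s.mouse_id: s.la_24h for s in summaries}, name="la_24h")


def window_annotations(summaries: Sequence[ActivitySummary]) -> pd.Series:
    """Light/dark annotation per window (same for every mouse sampled at ZT6)."""
    first = summaries[0]
    return first.la_3h["phase"].copy()


# ---------------------------------------------------------------------------
# tabular IO

def write_traces(traces: Sequence[ActivityTrace], traces_path, samples_path, conf_hash: str = "") -> None:
    """Long-format trace table plus a samples table with sampling times."""
    frames = []
    for t in traces:
        frames.append(
            pd.DataFrame(
                {"mouse_id": t.mouse_id, "bin_start_h": t.bin_starts, "distance_cm": t.distances}
            )
        )
    long = pd.concat(frames, ignore_index=True)
    write_table(long, traces_path, stage="activity:traces", conf_hash=conf_hash, index=False)
    samples = pd.DataFrame(
        {"mouse_id": [t.mouse_id for t in traces], "sampling_time_h": [t.sampling_time for t in traces]}
    )
    write_table(samples, samples_path, stage="activity:samples", conf_hash=conf_hash, index=False)


def read_traces(traces_path, samples_path) -> list[ActivityTrace]:
    long = read_table(traces_path, index_col=None)
    samples = read_table(samples_path, index_col=None)
    required = {"mouse_id", "bin_start_h", "distance_cm"}
    if not required.issubset(long.columns):
        raise ParseError(f"trace table must have columns {sorted(required)}")
    sampling = dict(zip(samples["mouse_id"].astype(str), samples["sampling_time_h"]))
    traces = []
    for mouse_id, grp in long.groupby("mouse_id", sort=False):
        mid = str(mouse_id)
        if mid not in sampling:
            raise ParseError(f"no sampling time for mouse {mid}")
        grp = grp.sort_values("bin_start_h")
        starts = grp["bin_start_h"].to_numpy(float)
        if len(starts) < 2:
            raise ParseError(f"{mid}: trace too short")
        traces.append(
            ActivityTrace(
                mouse_id=mid,
                bin_starts=starts,
                distances=grp["distance_cm"].to_numpy(float),
                bin_hours=float(starts[1] - starts[0]),
                sampling_time=float(sampling[mid]),
            )
        )
    return traces
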