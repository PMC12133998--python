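"""Descriptive statistics over time-locked bins.

The event-related approach summarizes each trial's time series over short
bins (e.g. 150 ms) anchored on a recurring event — typically the response
or stimulus onset.  Bin boundaries are given in ms relative to the anchor
and tile a half-open window: bin ``[start, end)`` holds the samples whose
time ``t = (s - anchor) * 1000 / fs`` satisfies ``start <= t < end``, so
each sample is counted exactly once and ``t = 0`` falls in the bin whose
interval contains 0.  At 1000 Hz a 150-ms bin holds exactly 150 samples.

Statistics are pure functions of the raw slice — the defaults are the
mean, the sample standard deviation (n−1 denominator), and the range
(max − min, a single non-negative scalar) — and users may register their
own.  Trials without a lock event, or bins left empty by trial edges,
yield missing values, never silent zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .fileio import KEY_COLUMNS
from .segmentation import TrialSegment

__all__ = [
    "BinSpec",
    "STATISTICS",
    "resolve_bins",
    "locate_lock",
    "compute_bin_stats",
    "bin_label",
]

#: Registry of named bin statistics: pure functions slice -> scalar.
STATISTICS: dict[str, Callable[[np.ndarray], float]] = {
    "mean": lambda x: float(np.mean(x)),
    "sd": lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else float("nan"),
    "range": lambda x: float(np.max(x) - np.min(x)),
}


@dataclass(frozen=True)
class BinSpec:
    """Bins, lock event, channels and statistics for one analysis.

    Defaults reproduce a response-locked analysis of the plate moments:
    lock on the response triggers {32, 64}, two 150-ms bins spanning
    [−150, 150) ms, channels Mx and My, statistics mean/sd/range.
    """

    lock_triggers: tuple[int, ...] = (32, 64)
    boundaries_ms: tuple[float, ...] = (-150.0, 150.0)
    bin_width_ms: float = 150.0
    vars: tuple[str, ...] = ("Mx", "My")
    statistics: tuple[str, ...] = ("mean", "sd", "range")
    lock_which: str = "first"  # or "last", for multi-subtask designs
    extra_statistics: dict[str, Callable[[np.ndarray], float]] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_width_ms <= 0:
            raise ValueError("bin_width_ms must be > 0")
        if len(self.boundaries_ms) < 2:
            raise ValueError("need at least two bin boundaries")
        if any(b <= a for a, b in zip(self.boundaries_ms, self.boundaries_ms[1:])):
            raise ValueError("boundaries must be strictly increasing")
        if self.lock_which not in ("first", "last"):
            raise ValueError("lock_which must be 'first' or 'last'")
        unknown = [s for s in self.statistics
                   if s not in STATISTICS and s not in self.extra_statistics]
        if unknown:
            raise ValueError(f"unknown statistics {unknown}; register them "
                             "via extra_statistics")

    def stat_fn(self, name: str) -> Callable[[np.ndarray], float]:
        return self.extra_statistics.get(name) or STATISTICS[name]


def resolve_bins(spec: BinSpec) -> list[tuple[float, float]]:
    """Tile [first boundary, last boundary) with half-open bins.

    Bins are locked to the anchor, so every boundary must sit on the
    bin-width grid through t = 0 (which also makes the span divisible by
    the width); e.g. boundaries (−150, 150) with width 150 yield
    [−150, 0) and [0, 150), while (−150, 150) with width 100 is rejected.
    """
    for b in spec.boundaries_ms:
        frac = b / spec.bin_width_ms
        if abs(frac - round(frac)) > 1e-9:
            raise ValueError(
                f"boundary {b} ms is not divisible by bin width "
                f"{spec.bin_width_ms} ms: bins must align with the anchor")
    first, last = spec.boundaries_ms[0], spec.boundaries_ms[-1]
    n_bins = int(round((last - first) / spec.bin_width_ms))
    edges = first + spec.bin_width_ms * np.arange(n_bins + 1)
    return [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]


def bin_label(start_ms: float, end_ms: float) -> str:
    """Human-readable column tag for the bin [start, end) in ms."""
    fmt = lambda v: f"{v:g}"
    return f"[{fmt(start_ms)},{fmt(end_ms)})"


def locate_lock(seg: TrialSegment, lock_triggers: Sequence[int],
                which: str = "first") -> int | None:
    """Onset sample of the trial's lock event, or None when absent."""
    ev = seg.find_event(list(lock_triggers), which=which)
    return None if ev is None else ev.onset_sample


def _bin_slice(series: np.ndarray, anchor: int, start_ms: float,
               end_ms: float, fs: float) -> np.ndarray:
    # sample s is in the bin iff start <= (s - anchor)*1000/fs < end
    lo = anchor + int(np.ceil(start_ms * fs / 1000.0))
    hi = anchor + int(np.ceil(end_ms * fs / 1000.0))  # exclusive
    return series[max(lo, 0):max(hi, 0)]


def compute_bin_stats(segments: Sequence[TrialSegment],
                      spec: BinSpec) -> pd.DataFrame:
    """Compute every (variable × bin × statistic) scalar for each trial.

    Returns a table with one row per trial keyed by (subject, block,
    trial), condition-label and flag columns, and one column per
    ``<var>_<bin>_<stat>``.  Bins truncated by the trial edges use the
    available samples and set the ``truncated`` flag; trials without a
    lock event carry missing values throughout.
    """
    bins = resolve_bins(spec)
    rows = []
    for seg in segments:
        unknown = [v for v in spec.vars if v not in seg.channels]
        if unknown:
            raise KeyError(f"trial {seg.trial}: unknown variables {unknown}")
        row: dict = {
            "subject": seg.id.subject,
            "block": seg.id.block if seg.id.block is not None else pd.NA,
            "trial": seg.trial,
            "complete": seg.complete,
            "truncated": False,
        }
        row.update({f"cond_{k}": v for k, v in seg.conditions.items()})
        anchor = locate_lock(seg, spec.lock_triggers, spec.lock_which)
        if anchor is None:
            warnings.warn(
                f"trial {seg.trial} (subj {seg.id.subject}): no lock event "
                f"among codes {spec.lock_triggers}; statistics set to "
                "missing", stacklevel=2)
        for var in spec.vars:
            series = seg.channels[var]
            for start_ms, end_ms in bins:
                label = bin_label(start_ms, end_ms)
                if anchor is None:
                    sl = np.empty(0)
                else:
                    sl = _bin_slice(series, anchor, start_ms, end_ms,
                                    seg.sampling_rate)
                    expected = int(round(
                        (end_ms - start_ms) * seg.sampling_rate / 1000.0))
                    if len(sl) < expected:
                        row["truncated"] = True
                for stat in spec.statistics:
                    col = f"{var}_{label}_{stat}"
                    row[col] = (spec.stat_fn(stat)(sl) if len(sl)
                                else np.nan)
        rows.append(row)
    df = pd.DataFrame(rows)
    for k in KEY_COLUMNS:
        if k in df.columns:
            df[k] = df[k].astype("Int64")
    return df
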