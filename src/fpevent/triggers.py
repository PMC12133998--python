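"""Parallel-port trigger decoding and event extraction.

Experimental software marks events (fixation onset, stimulus, response,
inter-trial interval) by setting the parallel port's pins; with ``N`` pins,
``2**N`` distinct codes are available.  Codes are *level-held*: a code stays
on the port until the next event replaces it, so the decoded code stream is
piecewise constant and a maximal constant run is one event.  Event onset is
the first sample at which a new code appears; all time-locking downstream
references onsets.  Code 0 (all pins low) is a legal event — typically the
inter-trial interval — not an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TriggerEvent",
    "decode_pin_levels",
    "encode_pin_levels",
    "extract_events",
    "suppress_glitches",
    "events_to_codes",
]


@dataclass(frozen=True)
class TriggerEvent:
    """A maximal run of one trigger code.

    ``onset_sample`` and ``offset_sample`` are 0-based and inclusive.
    """

    code: int
    onset_sample: int
    offset_sample: int

    def __post_init__(self) -> None:
        if self.onset_sample > self.offset_sample:
            raise ValueError("onset_sample must be <= offset_sample")
        if self.code < 0:
            raise ValueError("trigger code must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.offset_sample - self.onset_sample + 1

    def duration_ms(self, sampling_rate: float) -> float:
        return self.n_samples / sampling_rate * 1000.0


def decode_pin_levels(pin_volts: np.ndarray, threshold: float) -> np.ndarray:
    """Decode per-sample pin voltages into integer trigger codes.

    ``pin_volts`` has shape (n_samples, n_pins), least-significant pin
    first.  A pin counts as high when its voltage is strictly above
    ``threshold``; the code is the sum of ``2**p`` over high pins ``p``.
    """
    volts = np.atleast_2d(np.asarray(pin_volts, dtype=float))
    if volts.shape[1] < 1:
        raise ValueError("need at least one pin column")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    bad = ~np.isfinite(volts)
    if bad.any():
        i, p = np.argwhere(bad)[0]
        raise ValueError(f"non-finite pin voltage at sample {i}, pin {p}")
    weights = 2 ** np.arange(volts.shape[1], dtype=np.int64)
    return (volts > threshold) @ weights


def encode_pin_levels(codes: np.ndarray, n_pins: int = 8,
                      high: float = 5.0, low: float = 0.0) -> np.ndarray:
    """Encode integer codes as per-sample pin voltages (inverse of decoding).

    Returns an array of shape (n_samples, n_pins), LSB first.  Used by the
    synthetic generator to write pin-level raw files.
    """
    codes = np.asarray(codes, dtype=np.int64)
    if np.any(codes < 0) or np.any(codes >= 2 ** n_pins):
        raise ValueError(f"codes must lie in [0, {2 ** n_pins - 1}]")
    bits = (codes[:, None] >> np.arange(n_pins)) & 1
    return np.where(bits == 1, high, low).astype(float)


def extract_events(codes: np.ndarray, sampling_rate: float) -> list[TriggerEvent]:
    """Run-length encode a trigger-code series into ordered events.

    Events tile the recording: consecutive events carry different codes,
    there are no gaps or overlaps, and concatenating them reproduces the
    code series exactly.
    """
    codes = np.asarray(codes)
    if codes.size == 0:
        raise ValueError("trigger code series is empty")
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [codes.size - 1]))
    return [TriggerEvent(int(codes[s]), int(s), int(e))
            for s, e in zip(starts, ends)]


def suppress_glitches(events: list[TriggerEvent], min_duration_ms: float,
                      sampling_rate: float) -> list[TriggerEvent]:
    """Merge events shorter than ``min_duration_ms`` into their neighbour.

    Transient codes can appear for a sample or two while pins switch; runs
    shorter than the threshold are absorbed into the preceding event (the
    following one if the recording *starts* with a glitch, with a warning).
    ``min_duration_ms = 0`` returns the input unchanged.  Adjacent runs that
    end up with equal codes are re-merged, so the output still tiles the
    recording with strictly alternating codes.
    """
    if min_duration_ms < 0:
        raise ValueError("min_duration_ms must be >= 0")
    if min_duration_ms == 0 or len(events) <= 1:
        return list(events)

    min_samples = min_duration_ms / 1000.0 * sampling_rate
    kept: list[TriggerEvent] = []
    pending_prefix = 0  # glitch samples at the very start, absorbed forward
    for ev in events:
        if ev.n_samples < min_samples:
            if kept:
                prev = kept[-1]
                kept[-1] = TriggerEvent(prev.code, prev.onset_sample,
                                        ev.offset_sample)
            else:
                warnings.warn(
                    "recording starts with a sub-threshold trigger run; "
                    "merging it into the following event", stacklevel=2)
                pending_prefix = ev.n_samples
            continue
        onset = ev.onset_sample - pending_prefix
        pending_prefix = 0
        if kept and kept[-1].code == ev.code:
            prev = kept[-1]
            kept[-1] = TriggerEvent(prev.code, prev.onset_sample,
                                    ev.offset_sample)
        else:
            kept.append(TriggerEvent(ev.code, onset, ev.offset_sample))
    if not kept:
        # every run was sub-threshold: keep the longest as a single event
        longest = max(events, key=lambda e: e.n_samples)
        kept = [TriggerEvent(longest.code, events[0].onset_sample,
                             events[-1].offset_sample)]
    return kept


def events_to_codes(events: list[TriggerEvent]) -> np.ndarray:
    """Reconstruct the per-sample code series from a tiling event list."""
    n = events[-1].offset_sample + 1
    codes = np.empty(n, dtype=np.int64)
    for ev in events:
        codes[ev.onset_sample:ev.offset_sample + 1] = ev.code
    return codes
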