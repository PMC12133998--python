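"""Trial segmentation and baseline correction.

A continuous (filtered) recording is cut into per-trial epochs anchored on
a start trigger — here the fixation-cross onset.  Trial *i* spans from the
i-th start-trigger onset (inclusive) to the sample before the (i+1)-th
onset; the final trial runs to the end of the recording, and any samples
before the first start trigger belong to no trial.  Within-trial events are
re-expressed relative to the trial start, condition labels are resolved
from trigger codes, and trials missing an expected event class are kept but
flagged incomplete — exclusion is the analyst's decision, never implicit.

Baseline correction subtracts, per channel, the mean over a fixed interval
after the baseline-trigger onset (the fixation interval, a phase without
cognitive or muscular demands) from the whole trial.  The interval is
closed in ms at sample resolution: at 1000 Hz, [0, 215] averages exactly
216 samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .fileio import RawRecording, SubjectBlockID
from .triggers import TriggerEvent

__all__ = [
    "SegmentationSpec",
    "TrialSegment",
    "segment_recording",
    "baseline_correct",
    "add_derived_variable",
    "UNKNOWN_LABEL",
]

#: Label assigned when a condition map has no entry for an observed code.
UNKNOWN_LABEL = "unknown"


@dataclass(frozen=True)
class SegmentationSpec:
    """Trigger vocabulary and baseline settings for one experiment.

    Defaults reproduce a Simon-task posturography design: fixation onset
    (code 128) both starts a trial and anchors the baseline; stimulus
    identity/position is one of {1, 2, 4, 8}; the response is coded correct
    (32) or incorrect (64); code 0 is the inter-trial interval.  The same
    code may serve as start and baseline trigger, in which case the
    baseline anchors on the trial's own start onset.
    """

    start_triggers: tuple[int, ...] = (128,)
    stimulus_triggers: tuple[int, ...] = (1, 2, 4, 8)
    response_triggers: tuple[int, ...] = (32, 64)
    baseline_trigger: int = 128
    baseline_interval_ms: tuple[float, float] = (0.0, 215.0)
    n_trials_expected: int | None = None
    condition_maps: Mapping[str, Mapping[int, str]] = field(
        default_factory=lambda: {
            "stimulus": {1: "left-A", 2: "left-B", 4: "right-A", 8: "right-B"},
            "correctness": {32: "correct", 64: "incorrect"},
        }
    )

    def __post_init__(self) -> None:
        if not self.start_triggers:
            raise ValueError("start_triggers must be non-empty")
        a, b = self.baseline_interval_ms
        if a > b:
            raise ValueError("baseline interval must satisfy a <= b")
        if self.n_trials_expected is not None and self.n_trials_expected < 1:
            raise ValueError("n_trials_expected must be positive")


@dataclass
class TrialSegment:
    """One trial's epoch: channels, events and resolved condition labels.

    ``events`` carry onsets relative to the trial's first sample;
    ``start_sample`` records where the trial began in the parent recording.
    ``trial`` is 1-based within (subject, block).
    """

    id: SubjectBlockID
    trial: int
    sampling_rate: float
    start_sample: int
    channels: dict[str, np.ndarray]
    events: list[TriggerEvent]
    conditions: dict[str, str] = field(default_factory=dict)
    complete: bool = True
    baseline_applied: bool = False
    baseline_missing: bool = False

    def __post_init__(self) -> None:
        n = self.n_samples
        for ev in self.events:
            if not (0 <= ev.onset_sample <= ev.offset_sample < n):
                raise ValueError(
                    f"event {ev} outside trial sample range [0, {n})"
                )

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    def find_event(self, codes: Sequence[int], which: str = "first"
                   ) -> TriggerEvent | None:
        """First (or last) within-trial event whose code is in ``codes``."""
        matches = [ev for ev in self.events if ev.code in codes]
        if not matches:
            return None
        return matches[0] if which == "first" else matches[-1]


def _resolve_conditions(events: list[TriggerEvent],
                        condition_maps: Mapping[str, Mapping[int, str]]
                        ) -> dict[str, str]:
    # pure lookup: the first event whose code a map knows wins; a trial
    # with no mapped code gets the explicit unknown label
    out: dict[str, str] = {}
    for name, cmap in condition_maps.items():
        label = UNKNOWN_LABEL
        for ev in events:
            if ev.code in cmap:
                label = cmap[ev.code]
                break
        out[name] = label
    return out


def segment_recording(rec: RawRecording, events: list[TriggerEvent],
                      spec: SegmentationSpec) -> list[TrialSegment]:
    """Split a recording into per-trial segments at start-trigger onsets.

    Raises
    ------
    ValueError
        If no start-trigger event exists.

    Warns when the observed trial count differs from
    ``spec.n_trials_expected`` (processing continues with the observed
    trials).
    """
    onsets = [ev.onset_sample for ev in events
              if ev.code in spec.start_triggers]
    if not onsets:
        raise ValueError(
            f"no start-trigger event (codes {spec.start_triggers}) found"
        )
    if spec.n_trials_expected is not None and len(onsets) != spec.n_trials_expected:
        warnings.warn(
            f"expected {spec.n_trials_expected} trials but found "
            f"{len(onsets)} start-trigger onsets; proceeding with "
            f"{len(onsets)}", stacklevel=2)

    bounds = onsets + [rec.n_samples]
    segments: list[TrialSegment] = []
    for i, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
        trial_events = [
            TriggerEvent(ev.code,
                         max(ev.onset_sample, lo) - lo,
                         min(ev.offset_sample, hi - 1) - lo)
            for ev in events
            if ev.onset_sample < hi and ev.offset_sample >= lo
        ]
        has_stim = any(ev.code in spec.stimulus_triggers for ev in trial_events)
        has_resp = any(ev.code in spec.response_triggers for ev in trial_events)
        segments.append(TrialSegment(
            id=rec.id,
            trial=i,
            sampling_rate=rec.sampling_rate,
            start_sample=lo,
            channels={name: series[lo:hi].copy()
                      for name, series in rec.channels.items()},
            events=trial_events,
            conditions=_resolve_conditions(trial_events, spec.condition_maps),
            complete=has_stim and has_resp,
        ))
    return segments


def baseline_correct(seg: TrialSegment, spec: SegmentationSpec,
                     vars: Sequence[str] | None = None) -> TrialSegment:
    """Subtract the baseline-interval mean from each listed channel.

    The interval ``[a, b]`` is in ms relative to the baseline-trigger onset
    and closed at sample resolution.  If the baseline trigger is absent the
    channels are left uncorrected and the trial is flagged; an interval
    reaching past the trial end is truncated to the available samples.
    Correcting twice is a no-op beyond float noise (the interval mean is
    already ~0 after the first pass).
    """
    names = list(vars) if vars is not None else list(seg.channels)
    unknown = [n for n in names if n not in seg.channels]
    if unknown:
        raise KeyError(f"unknown channels {unknown}")

    anchor_ev = seg.find_event([spec.baseline_trigger])
    if anchor_ev is None:
        warnings.warn(
            f"trial {seg.trial} (subj {seg.id.subject}): baseline trigger "
            f"{spec.baseline_trigger} absent; channels left uncorrected",
            stacklevel=2)
        return replace(seg, baseline_missing=True)

    a_ms, b_ms = spec.baseline_interval_ms
    fs = seg.sampling_rate
    lo = anchor_ev.onset_sample + int(np.ceil(a_ms * fs / 1000.0))
    hi = anchor_ev.onset_sample + int(np.floor(b_ms * fs / 1000.0))  # inclusive
    if hi >= seg.n_samples or lo < 0:
        warnings.warn(
            f"trial {seg.trial}: baseline interval [{a_ms}, {b_ms}] ms "
            "exceeds trial bounds; truncating", stacklevel=2)
        lo, hi = max(lo, 0), min(hi, seg.n_samples - 1)
    if hi < lo:
        warnings.warn(f"trial {seg.trial}: empty baseline interval after "
                      "truncation; channels left uncorrected", stacklevel=2)
        return replace(seg, baseline_missing=True)

    corrected = dict(seg.channels)
    for name in names:
        series = seg.channels[name]
        corrected[name] = series - series[lo:hi + 1].mean()
    return replace(seg, channels=corrected, baseline_applied=True)


def add_derived_variable(segments: list[TrialSegment], name: str,
                         transform: Callable[..., np.ndarray]
                         ) -> list[TrialSegment]:
    """Append a per-sample derived channel to every segment.

    ``transform`` receives the existing channels as keyword arguments
    (matched by name against its signature) and must return a series of the
    trial's length.  Existing channels are untouched; a name collision is
    an error.
    """
    import inspect

    params = list(inspect.signature(transform).parameters)
    out: list[TrialSegment] = []
    for seg in segments:
        if name in seg.channels:
            raise ValueError(f"channel {name!r} already exists")
        missing = [p for p in params if p not in seg.channels]
        if missing:
            raise KeyError(f"transform references unknown channels {missing}")
        new = np.asarray(
            transform(**{p: seg.channels[p] for p in params}), dtype=float)
        if len(new) != seg.n_samples:
            raise ValueError(
                f"derived channel {name!r} has length {len(new)}, "
                f"expected {seg.n_samples}")
        channels = dict(seg.channels)
        channels[name] = new
        out.append(replace(seg, channels=channels))
    return out
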