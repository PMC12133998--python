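"""Zero-phase low-pass filtering with a reversed-prefix pad.

Force-plate channels are low-pass filtered before segmentation to remove
muscle-twitch and electromagnetic artifacts; the conventional choice for
kinesiological data, and the default here, is a fourth-order Butterworth
with a 10 Hz cutoff.  To cancel the IIR filter's phase lag the filter runs
forward and backward (squaring the magnitude response), and to absorb the
start-up transient of each pass the first ``pad_count`` samples (default
2000) are prepended *in reverse order* before the pass and dropped
afterwards.  With ``pad_count=0`` the scheme degenerates to plain
forward-backward filtering.

Any stable rational filter can be substituted for the default Butterworth
via :class:`FilterCoefficients`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "FilterSpec",
    "FilterCoefficients",
    "design_lowpass_butterworth",
    "frequency_response_magnitude",
    "zero_phase_filter_mirrored",
    "filter_recording",
]


@dataclass(frozen=True)
class FilterSpec:
    """Design parameters of the default low-pass Butterworth filter."""

    sampling_rate: float
    order: int = 4
    cutoff_hz: float = 10.0
    pad_count: int = 2000

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be > 0")
        if self.cutoff_hz >= self.sampling_rate / 2:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must lie below the Nyquist "
                f"frequency {self.sampling_rate / 2} Hz"
            )
        if self.pad_count < 0:
            raise ValueError("pad_count must be >= 0")


@dataclass(frozen=True)
class FilterCoefficients:
    """Numerator/denominator of a discrete rational transfer function.

    The denominator is normalized to a leading coefficient of 1 and the
    filter must be stable (all poles strictly inside the unit circle).
    """

    b: tuple[float, ...]
    a: tuple[float, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.size == 0 or b.size == 0:
            raise ValueError("coefficient arrays must be non-empty")
        if a[0] == 0:
            raise ValueError("leading denominator coefficient must be nonzero")
        if not np.allclose(a[0], 1.0):
            object.__setattr__(self, "b", tuple(b / a[0]))
            object.__setattr__(self, "a", tuple(a / a[0]))
        poles = np.roots(np.asarray(self.a))
        if poles.size and np.max(np.abs(poles)) >= 1.0:
            raise ValueError("unstable filter: pole on or outside the unit circle")

    @property
    def order(self) -> int:
        return max(len(self.a), len(self.b)) - 1


def design_lowpass_butterworth(spec: FilterSpec) -> FilterCoefficients:
    """Design the discrete low-pass Butterworth filter for ``spec``.

    Uses the bilinear transform with frequency prewarping, so the
    single-pass magnitude at ``cutoff_hz`` is exactly ``2**-0.5`` and the
    DC gain is 1.
    """
    b, a = signal.butter(spec.order, spec.cutoff_hz,
                         btype="low", fs=spec.sampling_rate)
    return FilterCoefficients(tuple(b), tuple(a))


def frequency_response_magnitude(coeffs: FilterCoefficients, freq_hz: float,
                                 sampling_rate: float) -> float:
    """Single-pass gain |H| at ``freq_hz``, evaluated on the unit circle."""
    _, h = signal.freqz(coeffs.b, coeffs.a, worN=[freq_hz], fs=sampling_rate)
    return float(np.abs(h[0]))


def zero_phase_filter_mirrored(x: np.ndarray, coeffs: FilterCoefficients,
                               pad_count: int = 2000) -> np.ndarray:
    """Filter ``x`` forward and backward with a reversed-prefix pad.

    Each pass prepends the series' first ``k = min(pad_count, len(x) - 1)``
    samples in reverse order, runs the filter with zero initial conditions,
    and drops the ``k`` padded outputs; the backward pass applies the same
    prepend-filter-drop to the time-reversed series.  The output has the
    input's length, zero net phase shift, and two-pass magnitude |H|².
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D series")
    if len(x) < coeffs.order + 1:
        raise ValueError(
            f"series of length {len(x)} is too short for an order-"
            f"{coeffs.order} filter"
        )
    if pad_count < 0:
        raise ValueError("pad_count must be >= 0")

    def one_pass(y: np.ndarray) -> np.ndarray:
        k = min(pad_count, len(y) - 1)
        padded = np.concatenate((y[:k][::-1], y)) if k else y
        out = signal.lfilter(coeffs.b, coeffs.a, padded)
        return out[k:]

    forward = one_pass(x)
    return one_pass(forward[::-1])[::-1]


def filter_recording(recording, coeffs: FilterCoefficients,
                     pad_count: int = 2000, channels: list[str] | None = None):
    """Return a copy of a recording with (selected) channels filtered.

    Filtering is applied per channel to the whole continuous block, before
    any segmentation; trigger codes and time are untouched.
    """
    from .fileio import RawRecording  # local import avoids a cycle

    names = channels if channels is not None else list(recording.channels)
    filtered = {
        name: (zero_phase_filter_mirrored(series, coeffs, pad_count)
               if name in names else series.copy())
        for name, series in recording.channels.items()
    }
    return RawRecording(id=recording.id, sampling_rate=recording.sampling_rate,
                        time=recording.time.copy(), channels=filtered,
                        trigger_codes=recording.trigger_codes.copy())
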