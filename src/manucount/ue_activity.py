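"""Wrist-accelerometry "UE activity count" comparator.

The conventional upper-extremity activity metric counts peaks in a
running sum of absolute sample-to-sample acceleration changes.  With the
device defaults (0.25 s trailing window -> 13 samples at 52.6 Hz,
0.33 g peak threshold, at most 4 peaks per second) each accepted peak is
one "activity count".  Only differences of the acceleration enter, so a
constant gravity offset is immaterial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .sensor_model import FS_HZ


@dataclass(frozen=True)
class ActivityParams:
    window: float = 0.25  # seconds, trailing
    peak_threshold: float = 0.33  # g
    max_peaks_per_second: int = 4
    fs: float = FS_HZ
    #: "sum_axes": sum |delta| over the three axes (the convention of the
    #: activity-counts literature); "magnitude": |delta| of the vector.
    change_mode: str = "sum_axes"

    def __post_init__(self):
        if self.window <= 0 or self.peak_threshold <= 0:
            raise ConfigurationError("window and peak_threshold must be positive")
        if self.max_peaks_per_second < 1:
            raise ConfigurationError("max_peaks_per_second must be >= 1")
        if self.change_mode not in ("sum_axes", "magnitude"):
            raise ConfigurationError(f"unknown change_mode {self.change_mode!r}")

    @property
    def window_samples(self) -> int:
        """Window length in samples (13 at the nominal 52.6 Hz)."""
        return int(round(self.window * self.fs))


def activity_signal(accel, params: ActivityParams = ActivityParams()) -> np.ndarray:
    """Running sum of absolute acceleration changes, g.

    ``s[k]`` sums the per-sample changes over the trailing
    ``window_samples`` steps (partial windows near the start);
    ``s[0] = 0``.  Output has the same length as the input.
    """
    a = np.atleast_2d(np.asarray(accel, dtype=float))
    if a.shape[0] == 1 and a.size > 3:
        a = a.T
    n = a.shape[0]
    w = params.window_samples
    if n < w:
        warnings.warn(
            f"fewer samples ({n}) than the {w}-sample window; returning empty signal",
            stacklevel=2,
        )
        return np.empty(0)
    step = np.abs(np.diff(a, axis=0))
    change = np.linalg.norm(step, axis=1) if params.change_mode == "magnitude" else step.sum(axis=1)
    cum = np.concatenate(([0.0], np.cumsum(change)))
    s = np.empty(n)
    s[0] = 0.0
    idx = np.arange(1, n)
    s[1:] = cum[idx] - cum[np.maximum(idx - w, 0)]
    return s


def activity_count(
    accel, params: ActivityParams = ActivityParams(), t=None
) -> tuple[int, np.ndarray]:
    """Count activity peaks; returns ``(count, peak_times)``.

    A peak is a strict local maximum of the running sum above
    ``peak_threshold`` (plateaus take their first sample).  At most
    ``max_peaks_per_second`` peaks are accepted within any trailing
    one-second window.
    """
    s = activity_signal(accel, params)
    n = s.shape[0]
    if t is None:
        t = np.arange(n) / params.fs
    else:
        t = np.asarray(t, dtype=float)
    accepted: list[float] = []
    k = 1
    while k < n:
        if s[k] > params.peak_threshold and s[k] > s[k - 1]:
            # find end of any plateau of equal values
            j = k
            while j + 1 < n and s[j + 1] == s[k]:
                j += 1
            is_peak = j + 1 >= n or s[j + 1] < s[k]
            if is_peak:
                tk = float(t[k])
                recent = sum(1 for ta in accepted if tk - ta < 1.0)
                if recent < params.max_peaks_per_second:
                    accepted.append(tk)
            k = j + 1
        else:
            k += 1
    return len(accepted), np.asarray(accepted)
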