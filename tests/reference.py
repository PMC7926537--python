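"""Independent, deliberately naive reference implementations.

These transliterate the counting rules sample by sample with explicit
state variables and plain Python lists.  They are slower and structured
differently from the package implementation so they can serve as
brute-force oracles in the tests.
"""

from __future__ import annotations

import numpy as np
from scipy import signal


def reference_filter(d, lp_cutoff, fs):
    """Causal 2nd-order Butterworth per axis, steady-state init at x[0]."""
    d = np.asarray(d, float)
    if lp_cutoff is None:
        return d.copy()
    b, a = signal.butter(2, lp_cutoff, fs=fs)
    zi = signal.lfilter_zi(b, a)
    out = np.empty_like(d)
    for axis in range(d.shape[1]):
        out[:, axis], _ = signal.lfilter(b, a, d[:, axis], zi=zi * d[0, axis])
    return out


def reference_hand_count(t, d, threshold, n_two, n_one, lp_cutoff, fs, reset_timeout=2.0):
    """Literal replay of the counting rules; returns a list of event dicts.

    Per axis: the change between consecutive filtered samples is
    classified as positive, negative, or ignored (|change| <= threshold).
    Same-direction changes extend a run, opposite ones restart it.  A
    count fires when two axes hold runs >= n_two at the same sample, or
    one axis holds a run >= n_one.  After a count everything is cleared
    and counting stays off until a triggering axis reverses with a
    supra-threshold change or reset_timeout elapses.
    """
    y = reference_filter(d, lp_cutoff, fs)
    direction = [0, 0, 0]
    run = [0, 0, 0]
    armed = True
    last_event_time = None
    trigger_axes: list[tuple[int, int]] = []
    events = []
    for k in range(1, len(t)):
        changes = [y[k][a] - y[k - 1][a] for a in range(3)]
        if not armed:
            if t[k] - last_event_time >= reset_timeout:
                armed = True
            else:
                for a, d_at_trigger in trigger_axes:
                    c = changes[a]
                    if abs(c) > threshold and np.sign(c) == -d_at_trigger:
                        armed = True
                        break
            if not armed:
                continue
        for a in range(3):
            c = changes[a]
            if abs(c) > threshold:
                s = int(np.sign(c))
                if s == direction[a]:
                    run[a] += 1
                else:
                    direction[a] = s
                    run[a] = 1
        two = [a for a in range(3) if run[a] >= n_two]
        one = [a for a in range(3) if run[a] >= n_one]
        if len(two) >= 2:
            events.append({"t": t[k], "trigger": "two_axes", "axes": tuple(two)})
            trigger_axes = [(a, direction[a]) for a in two]
        elif one:
            events.append({"t": t[k], "trigger": "one_axis", "axes": tuple(one)})
            trigger_axes = [(a, direction[a]) for a in one]
        else:
            continue
        direction = [0, 0, 0]
        run = [0, 0, 0]
        armed = False
        last_event_time = t[k]
    return events


def reference_run_lengths(deltas, threshold):
    """Same-direction run lengths of one axis's change sequence."""
    lengths = []
    current_sign = 0
    current_len = 0
    for c in deltas:
        if abs(c) <= threshold:
            continue
        s = 1 if c > 0 else -1
        if s == current_sign:
            current_len += 1
        else:
            if current_len:
                lengths.append(current_len)
            current_sign = s
            current_len = 1
    if current_len:
        lengths.append(current_len)
    return lengths


def reference_activity_signal(accel, w):
    """Direct O(n*w) windowed sum of absolute acceleration changes."""
    a = np.asarray(accel, float)
    n = a.shape[0]
    step = [sum(abs(a[i][ax] - a[i - 1][ax]) for ax in range(a.shape[1])) for i in range(1, n)]
    s = [0.0] * n
    for k in range(1, n):
        lo = max(0, k - w)
        s[k] = sum(step[lo:k])
    return np.asarray(s)


def reference_peak_scan(t, s, threshold, max_per_second):
    """Brute-force peak scanner with the trailing one-second cap."""
    accepted = []
    k = 1
    n = len(s)
    while k < n:
        if s[k] > threshold and s[k] > s[k - 1]:
            j = k
            while j + 1 < n and s[j + 1] == s[k]:
                j += 1
            if j + 1 >= n or s[j + 1] < s[k]:
                if sum(1 for ta in accepted if t[k] - ta < 1.0) < max_per_second:
                    accepted.append(t[k])
            k = j + 1
        else:
            k += 1
    return accepted
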