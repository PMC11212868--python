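"""Diastolic baseline-window location shared by the strain pipeline and the
trace generator's gain calibration (both must measure strain identically)."""
from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d

#: duration of the quiescent averaging window (5 frames at 90 fps)
WINDOW_S = 5.0 / 90.0
#: backoff between the detected threshold crossing and the window end
#: (4 frames at 90 fps) — keeps the window clear of the contraction rise
#: and of the moving-average shift at any sampling rate
BACKOFF_S = 4.0 / 90.0


def baseline_window(provisional_strain: np.ndarray, threshold: float = 0.5,
                    dt: float = 1.0 / 90.0) -> slice:
    """Window of quiescent samples preceding contraction onset.

    The provisional strain (percent, relative to the first sample) is
    smoothed with a moving average; onset is the first run of three
    consecutive smoothed samples above the threshold, and the window is the
    fixed-duration span ending a fixed backoff before that crossing.  Both
    spans are defined in time so baselines agree across sampling rates, and
    the backoff keeps the window unbiased even when noise defeats any
    amplitude-based quiet-point criterion.  Falls back to the first sample
    when the onset is too early or never found.
    """
    prov = np.abs(np.asarray(provisional_strain, dtype=float))
    w = max(3, int(round(WINDOW_S / dt)))
    smooth = uniform_filter1d(prov, w, mode="nearest")
    above = smooth > threshold
    run = above & np.roll(above, -1) & np.roll(above, -2)
    run[-2:] = False
    hits = np.flatnonzero(run)
    if len(hits) == 0:
        return slice(0, 1)
    end = hits[0] - max(2, int(round(BACKOFF_S / dt)))
    if end < 1:
        return slice(0, 1)
    return slice(max(end - w, 0), end)
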