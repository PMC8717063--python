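"""Canonical double-gamma hemodynamic response function and convolution.

The canonical HRF is the difference of two gamma densities — a positive
response peaking ~5 s after stimulus onset and a later, smaller
undershoot — with the standard parameterization (response delay 6,
undershoot delay 16, unit dispersions, undershoot ratio 1/6, all in
seconds for a unit dispersion).  Event regressors are built by convolving
a boxcar of the event's onset/duration with this kernel on an oversampled
grid, then sampling at the scan acquisition times.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def canonical_hrf(time_grid, peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                  peak_dispersion: float = 1.0, undershoot_dispersion: float = 1.0,
                  undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Evaluate the double-gamma HRF on nonnegative times (seconds).

    The response is normalized to unit peak amplitude.  With the default
    parameters the peak sits near 5 s and the response has decayed to
    ~0 by 32 s.  Negative times are rejected.
    """
    t = np.asarray(time_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("canonical_hrf requires nonnegative times")

    def raw(tt):
        peak = stats.gamma.pdf(tt, a=peak_delay / peak_dispersion,
                               scale=peak_dispersion)
        under = stats.gamma.pdf(tt, a=undershoot_delay / undershoot_dispersion,
                                scale=undershoot_dispersion)
        return peak - undershoot_ratio * under

    # unit-peak normalization from a dense reference grid
    ref = raw(np.arange(0.0, 32.0, 0.01))
    scale = float(np.max(ref))
    if scale <= 0:
        raise ValueError("degenerate HRF parameters: nonpositive peak")
    return raw(t) / scale


def hrf_regressor(onsets, durations, frame_times, amplitudes=None,
                  oversample: int = 10, **hrf_params) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at scan times.

    Parameters
    ----------
    onsets, durations
        Event onsets and durations in seconds (scalars broadcast).
    frame_times
        Acquisition times of the volumes (seconds, ascending).
    amplitudes
        Per-event amplitude (default 1).
    oversample
        Fine-grid resolution relative to the mean frame spacing.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.broadcast_to(np.asarray(durations, dtype=float), onsets.shape)
    frame_times = np.asarray(frame_times, dtype=float)
    if amplitudes is None:
        amplitudes = np.ones_like(onsets)
    else:
        amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), onsets.shape)

    if frame_times.size < 2:
        raise ValueError("need at least two frame times")
    dt = float(np.mean(np.diff(frame_times))) / oversample
    t_end = frame_times[-1] + 33.0
    fine = np.arange(0.0, t_end + dt, dt)
    box = np.zeros_like(fine)
    for on, dur, amp in zip(onsets, durations, amplitudes):
        if on < 0:
            raise ValueError("event onset before run start")
        box[(fine >= on) & (fine < on + dur)] += amp
    kernel = canonical_hrf(np.arange(0.0, 32.0 + dt, dt), **hrf_params)
    conv = np.convolve(box, kernel)[: fine.size] * dt
    return np.interp(frame_times, fine, conv)
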