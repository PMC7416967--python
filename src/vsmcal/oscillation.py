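"""Oscillation detection and period-averaged observables.

A trajectory is classified as oscillatory when, after discarding the initial
transient, the cytosolic-calcium trace has (i) half peak-to-trough amplitude
above a threshold (default 1e-3 uM, 1% of resting calcium) and (ii) a
dominant periodogram peak well above the median spectral power (default
ratio 10, rejecting broadband numerical ripple).  The experiment summaries
(bifurcation envelopes, period-averaged fluxes) are built on this
classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .simulate import Trajectory

__all__ = ["OscillationSummary", "detect_oscillation", "period_average",
           "dominant_period"]

TRANSIENT_END_DEFAULT = 600.0   # s; the reported transient is ~3 min
AMP_THRESHOLD = 1e-3            # uM, 1% of resting cytosolic calcium
PEAK_MEDIAN_RATIO = 10.0        # periodogram peak vs median power


@dataclass(frozen=True)
class OscillationSummary:
    oscillatory: bool
    amplitude: float                # uM, half peak-to-trough of Ca_cyt
    dominant_period: float | None   # s
    period_averaged: dict = field(default_factory=dict)
    transient_end: float = TRANSIENT_END_DEFAULT

    def to_dict(self) -> dict:
        return {
            "oscillatory": bool(self.oscillatory),
            "amplitude": float(self.amplitude),
            "dominant_period": (None if self.dominant_period is None
                                else float(self.dominant_period)),
            "period_averaged": {k: float(v)
                                for k, v in self.period_averaged.items()},
            "transient_end": float(self.transient_end),
        }


def _window(traj: Trajectory, transient_end: float,
            analysis_window: float | None):
    t = traj.times
    t_end = t[-1]
    if analysis_window is None:
        t_start = transient_end
    else:
        t_start = t_end - analysis_window
        if t_start < transient_end - 1e-9:
            raise ValueError(
                f"analysis window of {analysis_window} s does not fit after "
                f"the {transient_end} s transient in a {t_end} s trajectory")
    if t_start >= t_end:
        raise ValueError("trajectory shorter than the transient cutoff")
    sel = t >= t_start - 1e-9
    if sel.sum() < 8:
        raise ValueError("too few samples in the analysis window")
    return sel


def dominant_period(t: np.ndarray, x: np.ndarray,
                    peak_median_ratio: float = PEAK_MEDIAN_RATIO
                    ) -> float | None:
    """Dominant period of a uniformly sampled signal, or None.

    Hann-tapered periodogram, zero-padded 4x, with parabolic interpolation
    of the peak for sub-bin frequency resolution.  Returns None when the
    peak does not exceed ``peak_median_ratio`` times the median power.
    """
    dt = float(np.median(np.diff(t)))
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    nfft = int(4 * 2 ** np.ceil(np.log2(max(n, 2))))
    f, p = sps.periodogram(x, fs=1.0 / dt, window="hann", nfft=nfft,
                           detrend=False)
    f, p = f[1:], p[1:]                 # drop the zero-frequency bin
    if not np.any(p > 0):
        return None
    k = int(np.argmax(p))
    med = float(np.median(p))
    if med <= 0 or p[k] < peak_median_ratio * med:
        return None
    # parabolic interpolation around the peak (log power)
    if 0 < k < p.size - 1 and p[k - 1] > 0 and p[k + 1] > 0:
        la, lb, lc = np.log(p[k - 1]), np.log(p[k]), np.log(p[k + 1])
        denom = la - 2 * lb + lc
        shift = 0.5 * (la - lc) / denom if denom != 0 else 0.0
        shift = float(np.clip(shift, -0.5, 0.5))
    else:
        shift = 0.0
    f_peak = f[k] + shift * (f[1] - f[0])
    return float(1.0 / f_peak) if f_peak > 0 else None


def detect_oscillation(traj: Trajectory,
                       analysis_window: float | None = None,
                       transient_end: float = TRANSIENT_END_DEFAULT,
                       amp_threshold: float = AMP_THRESHOLD,
                       peak_median_ratio: float = PEAK_MEDIAN_RATIO,
                       observables: tuple = ("Ca_cyt",),
                       ) -> OscillationSummary:
    """Classify a trajectory and summarize its post-transient behaviour.

    ``analysis_window`` restricts the analysis to the trailing window of
    that length (default: everything after ``transient_end``).
    """
    sel = _window(traj, transient_end, analysis_window)
    t = traj.times[sel]
    c = traj.Ca_cyt[sel]
    amplitude = 0.5 * float(c.max() - c.min())
    period = dominant_period(t, c, peak_median_ratio)
    # a period is only credible if >= 2 full cycles fit the window;
    # slower spectral peaks are settling trends, not sustained oscillation
    if period is not None and period > 0.5 * (t[-1] - t[0]):
        period = None
    oscillatory = bool(amplitude > amp_threshold and period is not None)
    averaged = {
        name: _average(t, traj.observable(name)[sel],
                       period if oscillatory else None)
        for name in observables
    }
    return OscillationSummary(
        oscillatory=oscillatory, amplitude=amplitude,
        dominant_period=period if oscillatory else None,
        period_averaged=averaged,
        transient_end=float(t[0]),
    )


def _average(t: np.ndarray, x: np.ndarray, period: float | None) -> float:
    """Trailing time-average over whole periods (or the full window)."""
    span = t[-1] - t[0]
    if period is not None and period > 0:
        n_cycles = int(span / period)
        if n_cycles >= 1:
            t_start = t[-1] - n_cycles * period
            sel = t >= t_start - 1e-9
            t, x = t[sel], x[sel]
    if t.size < 2:
        return float(x[-1])
    return float(np.trapezoid(x, t) / (t[-1] - t[0]))


def period_average(traj: Trajectory, observable: str,
                   analysis_window: float | None = None,
                   transient_end: float = TRANSIENT_END_DEFAULT) -> float:
    """Time-average of one observable over whole cycles (or the window)."""
    summary = detect_oscillation(traj, analysis_window,
                                 transient_end=transient_end,
                                 observables=(observable,))
    return summary.period_averaged[observable]
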