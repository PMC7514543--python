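"""Event-related desynchronization / synchronization quantification.

For a set of trials the relative band-power change is computed per channel
as

    EEG_avg(j)  = (1/N) * sum_i s_ij^2          (trial-averaged power)
    EEG_ref     = mean of EEG_avg over a pre-cue reference interval
    ERD/ERS (%) = 100 * (EEG_avg(j) - EEG_ref) / EEG_ref

where s_ij is the j-th sample of the i-th band-pass-filtered trial.
Negative values are desynchronization (power loss relative to rest),
positive values synchronization.  Filtering is zero-phase (forward-
backward 4th-order Butterworth) so ERD latency is not shifted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from wavemi.synthetic import EpochSet

#: canonical sensorimotor bands, Hz
BANDS = {"mu": (8.0, 13.0), "beta": (13.0, 30.0), "mu+beta": (8.0, 30.0)}


@dataclass
class ERDCurve:
    """Relative band-power time course for one channel, in percent."""

    channel: str
    band: tuple[float, float]
    times: np.ndarray
    values: np.ndarray
    ref_interval: tuple[float, float]
    n_trials: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -100.0 - 1e-9):
            raise ValueError("relative power change cannot fall below -100%")

    def mean_over(self, t_start: float, t_end: float) -> float:
        """Mean percent change over [t_start, t_end] seconds."""
        mask = (self.times >= t_start) & (self.times <= t_end)
        if not mask.any():
            raise ValueError(f"interval [{t_start}, {t_end}] s selects no samples")
        return float(self.values[mask].mean())


def _bandpass(data: np.ndarray, fs: float, band: tuple[float, float],
              order: int = 4) -> np.ndarray:
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band {band} must lie within (0, {fs / 2}) Hz")
    sos = butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, data, axis=-1)


def average_power(epochs: EpochSet, band: tuple[float, float]) -> np.ndarray:
    """Trial-averaged instantaneous band power, (n_channels, n_samples).

    Each trial is band-pass filtered, squared sample-wise, and averaged
    across trials per time index.
    """
    if len(epochs) == 0:
        raise ValueError("need at least one epoch")
    filtered = _bandpass(epochs.data_array(), epochs.fs, band)
    return (filtered**2).mean(axis=0)


def reference_power(avg_power: np.ndarray, ref_interval: tuple[float, float],
                    fs: float) -> np.ndarray:
    """Mean of the average power over the reference interval (per channel)."""
    j0 = int(round(ref_interval[0] * fs))
    j1 = int(round(ref_interval[1] * fs))
    if not 0 <= j0 < j1 <= avg_power.shape[-1]:
        raise ValueError(
            f"reference interval {ref_interval} s is outside the series"
        )
    return avg_power[..., j0:j1].mean(axis=-1)


def erd_ers_percent(avg_power: np.ndarray, ref_power: float | np.ndarray
                    ) -> np.ndarray:
    """Relative power change in percent: 100 * (avg - ref) / ref."""
    ref = np.asarray(ref_power, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference power must be positive")
    if ref.ndim:
        ref = ref[..., None]
    return 100.0 * (avg_power - ref) / ref


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    pad = width // 2
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="edge")
    out = np.apply_along_axis(lambda r: np.convolve(r, kernel, "valid"), -1, xp)
    return out[..., : x.shape[-1]]


def erd_timecourse(
    epochs: EpochSet,
    band: tuple[float, float] | str = "mu",
    ref_interval: tuple[float, float] | None = None,
    smooth_s: float = 0.25,
) -> list[ERDCurve]:
    """ERD/ERS percent time course per channel.

    ``band`` is a (lo, hi) pair in Hz or one of 'mu', 'beta', 'mu+beta'.
    ``ref_interval`` defaults to the 1 s window ending 0.5 s before the
    cue.  The trial-averaged power is smoothed with a ``smooth_s``-long
    moving average before the percent change is formed.
    """
    if isinstance(band, str):
        band = BANDS[band]
    fs = epochs.fs
    cue = epochs.epochs[0].cue_onset_s
    if ref_interval is None:
        ref_interval = (max(0.0, cue - 1.5), max(0.0, cue - 0.5))

    avg = average_power(epochs, band)
    avg = _moving_average(avg, int(round(smooth_s * fs)))
    ref = reference_power(avg, ref_interval, fs)
    percent = erd_ers_percent(avg, ref)

    times = np.arange(avg.shape[-1]) / fs
    return [
        ERDCurve(
            channel=ch, band=band, times=times, values=percent[i],
            ref_interval=ref_interval, n_trials=len(epochs),
        )
        for i, ch in enumerate(epochs.channels)
    ]
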