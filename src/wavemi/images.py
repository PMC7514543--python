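"""Build CNN input images from per-electrode scalograms.

A motor-imagery trial becomes one real-valued image whose rows combine
electrode and frequency and whose columns are time.  For the dual-band
variant: the mu band (8-13 Hz, 26 rows at the default grid) and beta band
(13-30 Hz, 37 rows) are cut from each electrode's scalogram over the 2 s
task interval; the 0.5 s sub-window with the smallest total mu-band
magnitude across all three electrodes is selected; both bands are resized
with cubic splines (mu -> 15 rows, beta -> 16 rows, time -> 32 columns)
and concatenated into a 31 x 32 block per electrode; blocks stack C3, Cz,
C4 top to bottom into the 93 x 32 image.  The mu-only variant skips the
frequency resize (3 x 26 = 78 native rows) to preserve frequency detail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from wavemi.cwt import FrequencyGrid, MotherWavelet, Scalogram, cwt_forward
from wavemi.synthetic import CHANNELS, EEGEpoch

#: default analysis grids reproducing 26 mu rows and 37 beta rows over a
#: 2 s / 500-sample task interval
MU_BAND_GRID = FrequencyGrid.linear(8.0, 13.0, step=0.2)
BETA_BAND_GRID = FrequencyGrid.linear(13.0, 30.0, num=37)

#: fixed output geometry of the dual-band image
DUAL_MU_ROWS = 15
DUAL_BETA_ROWS = 16
TIME_COLS = 32
WINDOW_S = 0.5


@dataclass
class MIImage:
    """The Nv x Nt image fed to the CNN, with per-row provenance.

    ``row_map`` lists, for every row, the (electrode, band, frequency Hz)
    it was interpolated from; resized rows carry the interpolated grid
    frequency.
    """

    values: np.ndarray
    row_map: list[tuple[str, str, float]]
    window: tuple[float, float]
    label: str | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("image values must be 2-D")
        if len(self.row_map) != self.values.shape[0]:
            raise ValueError(
                f"row_map length {len(self.row_map)} != {self.values.shape[0]} rows"
            )
        if self.normalized and self.values.size:
            if self.values.min() < 0 or self.values.max() > 1:
                raise ValueError("normalized image must lie in [0, 1]")

    @property
    def Nv(self) -> int:
        return self.values.shape[0]

    @property
    def Nt(self) -> int:
        return self.values.shape[1]


def extract_band(scalogram: Scalogram, f_lo: float, f_hi: float) -> Scalogram:
    """Rows of the scalogram with f_lo <= f <= f_hi, order preserved."""
    tol = 1e-6  # absorb float fuzz on grid endpoints (Hz)
    mask = (scalogram.freqs >= f_lo - tol) & (scalogram.freqs <= f_hi + tol)
    if not mask.any():
        raise ValueError(
            f"band [{f_lo}, {f_hi}] Hz selects no rows of the grid "
            f"[{scalogram.freqs[0]}, {scalogram.freqs[-1]}] Hz"
        )
    return Scalogram(
        channel=scalogram.channel,
        freqs=scalogram.freqs[mask],
        times=scalogram.times,
        values=scalogram.values[mask],
        wavelet=scalogram.wavelet,
        is_power=scalogram.is_power,
    )


def select_min_power_window(
    mu_bands: list[Scalogram], win_s: float = WINDOW_S
) -> tuple[int, int]:
    """Exhaustive stride-1 scan for the quietest mu-band window.

    Returns (start, end) column indices (end exclusive) of the contiguous
    window of length ``win_s`` seconds minimizing the total mu-band
    magnitude summed over frequencies and electrodes; ties break toward
    the earliest start.
    """
    fs = mu_bands[0].fs
    n_cols = mu_bands[0].values.shape[1]
    width = int(round(win_s * fs))
    if width > n_cols:
        raise ValueError(
            f"window of {width} columns exceeds the {n_cols} available"
        )
    total = np.zeros(n_cols)
    for sc in mu_bands:
        if sc.values.shape[1] != n_cols:
            raise ValueError("scalograms must share the time axis")
        total += sc.values.sum(axis=0)
    windowed = np.convolve(total, np.ones(width), mode="valid")
    start = int(np.argmin(windowed))  # argmin takes the first minimum
    return start, start + width


def resize_spline(matrix: np.ndarray, out_rows: int, out_cols: int) -> np.ndarray:
    """Cubic-spline resampling onto a uniform grid spanning the input extent.

    Interpolates independently along each axis (rows first, then columns)
    with not-a-knot cubic splines, which reproduce constants and linear
    ramps exactly.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("input must be at least 2 x 2")
    if not np.all(np.isfinite(m)):
        raise ValueError("input contains non-finite values")
    if out_rows < 1 or out_cols < 1:
        raise ValueError("output sizes must be >= 1")

    def _axis_resize(a: np.ndarray, out_n: int) -> np.ndarray:
        n = a.shape[0]
        if out_n == n:
            return a
        target = np.linspace(0, n - 1, out_n)
        return CubicSpline(np.arange(n), a, axis=0)(target)

    return _axis_resize(_axis_resize(m, out_rows).T, out_cols).T


def _check_electrodes(bands: list[Scalogram]) -> None:
    names = tuple(sc.channel for sc in bands)
    if names != CHANNELS:
        raise ValueError(f"expected electrodes {CHANNELS} in order, got {names}")


def _resized_row_freqs(freqs: np.ndarray, out_rows: int) -> np.ndarray:
    return np.interp(
        np.linspace(0, len(freqs) - 1, out_rows), np.arange(len(freqs)), freqs
    )


def build_image_dual(
    mu_bands: list[Scalogram],
    beta_bands: list[Scalogram],
    win_s: float = WINDOW_S,
    label: str | None = None,
) -> MIImage:
    """Dual-band image: (15 mu + 16 beta) rows x 32 columns per electrode,
    three electrodes stacked -> 93 x 32.

    The minimum-power window is chosen from the mu band only and applied
    unchanged to the beta band.
    """
    _check_electrodes(mu_bands)
    _check_electrodes(beta_bands)
    start, end = select_min_power_window(mu_bands, win_s)
    t0 = float(mu_bands[0].times[start])
    t1 = t0 + win_s

    blocks, row_map = [], []
    for mu_sc, beta_sc in zip(mu_bands, beta_bands):
        mu_part = resize_spline(mu_sc.values[:, start:end], DUAL_MU_ROWS, TIME_COLS)
        beta_part = resize_spline(beta_sc.values[:, start:end], DUAL_BETA_ROWS, TIME_COLS)
        blocks.append(np.vstack([mu_part, beta_part]))
        for f in _resized_row_freqs(mu_sc.freqs, DUAL_MU_ROWS):
            row_map.append((mu_sc.channel, "mu", float(f)))
        for f in _resized_row_freqs(beta_sc.freqs, DUAL_BETA_ROWS):
            row_map.append((beta_sc.channel, "beta", float(f)))

    return MIImage(np.vstack(blocks), row_map, window=(t0, t1), label=label)


def build_image_mu(
    mu_bands: list[Scalogram],
    win_s: float = WINDOW_S,
    label: str | None = None,
) -> MIImage:
    """Mu-only image: native mu rows (26 by default) x 32 columns per
    electrode, stacked -> 78 x 32 at the default grid."""
    _check_electrodes(mu_bands)
    start, end = select_min_power_window(mu_bands, win_s)
    t0 = float(mu_bands[0].times[start])

    blocks, row_map = [], []
    for sc in mu_bands:
        n_rows = sc.values.shape[0]
        blocks.append(resize_spline(sc.values[:, start:end], n_rows, TIME_COLS))
        for f in sc.freqs:
            row_map.append((sc.channel, "mu", float(f)))

    return MIImage(np.vstack(blocks), row_map, window=(t0, t0 + win_s), label=label)


def normalize_image(img: MIImage) -> MIImage:
    """Min-max scale the whole image to [0, 1] (trial-local, leak-free)."""
    lo, hi = img.values.min(), img.values.max()
    if hi > lo:
        values = (img.values - lo) / (hi - lo)
    else:
        warnings.warn("constant image; normalizing to all zeros",
                      RuntimeWarning, stacklevel=2)
        values = np.zeros_like(img.values)
    return MIImage(values, list(img.row_map), img.window, img.label, normalized=True)


def task_segment(epoch: EEGEpoch, task_window_s: tuple[float, float] = (0.5, 2.5)
                 ) -> np.ndarray:
    """The (n_channels, n_task_samples) slice of the cued imagery interval."""
    i0 = int(round((epoch.cue_onset_s + task_window_s[0]) * epoch.fs))
    i1 = int(round((epoch.cue_onset_s + task_window_s[1]) * epoch.fs))
    if i0 < 0 or i1 > epoch.n_samples:
        raise ValueError("task window lies outside the epoch")
    return epoch.data[:, i0:i1]


def build_trial_image(
    epoch: EEGEpoch,
    wavelet: MotherWavelet,
    variant: str = "dual",
    *,
    task_window_s: tuple[float, float] = (0.5, 2.5),
    mu_grid: FrequencyGrid = MU_BAND_GRID,
    beta_grid: FrequencyGrid = BETA_BAND_GRID,
    win_s: float = WINDOW_S,
    normalize: bool = True,
    power: bool = False,
) -> MIImage:
    """Full per-trial path: task segment -> CWT per band -> image.

    ``variant`` selects the dual-band (93 x 32) or mu-only (78 x 32)
    construction; the image is min-max normalized unless disabled.
    """
    if variant not in ("dual", "mu"):
        raise ValueError(f"variant must be 'dual' or 'mu', got {variant!r}")
    seg = task_segment(epoch, task_window_s)
    mu_bands = [
        cwt_forward(seg[i], epoch.fs, mu_grid, wavelet,
                    channel=epoch.channels[i], power=power)
        for i in range(len(epoch.channels))
    ]
    if variant == "mu":
        img = build_image_mu(mu_bands, win_s, label=epoch.label)
    else:
        beta_bands = [
            cwt_forward(seg[i], epoch.fs, beta_grid, wavelet,
                        channel=epoch.channels[i], power=power)
            for i in range(len(epoch.channels))
        ]
        img = build_image_dual(mu_bands, beta_bands, win_s, label=epoch.label)
    return normalize_image(img) if normalize else img
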