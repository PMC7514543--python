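"""Synthetic motor-imagery EEG with a controllable lateralized ERD/ERS effect.

Each epoch is three channels (C3, Cz, C4) of band-limited mu (8-13 Hz) and
beta (13-30 Hz) oscillations riding on 1/f ("pink") background noise.
During a cued imagery interval the oscillation amplitudes on the channel
contralateral to the imagined hand (C4 for left, C3 for right) are reduced
by a multiplicative factor -- the event-related desynchronization (ERD) --
and may rebound above baseline afterwards (ERS).  Because the amplitude
modulation is known analytically, every downstream estimator can be
checked against closed-form ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

CHANNELS = ("C3", "Cz", "C4")
LABELS = ("left", "right")

#: channel contralateral to each imagined hand
CONTRALATERAL = {"left": "C4", "right": "C3"}
IPSILATERAL = {"left": "C3", "right": "C4"}


@dataclass(frozen=True)
class ERDParams:
    """Generator settings for one study condition.

    The defaults mirror the geometry of a cued two-class motor-imagery
    recording at 250 Hz: 8 s epochs, visual cue at 3 s, imagery analysed
    in a 2 s interval 0.5-2.5 s after the cue.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz.
    duration_s : float
        Epoch length in seconds.
    cue_onset_s : float
        Cue time within the epoch, seconds.
    task_window_s : tuple of float
        (start, end) of the imagery interval relative to the cue, seconds.
    mu_freq, beta_freq : float
        Center frequencies of the two sensorimotor oscillators, Hz.
    mu_amp, beta_amp : float
        Baseline oscillation amplitudes (arbitrary units ~ uV).
    erd_attenuation : float
        Multiplicative amplitude factor in (0, 1] applied to the
        contralateral channel during the task window.  Band *power* scales
        with its square: attenuation 0.5 means a -75% ERD.
    ers_rebound : float
        Amplitude factor >= 1 applied after the task window (1 = no ERS).
    noise_sigma : float
        Standard deviation of the 1/f background noise.
    cz_mix : float
        Fraction in [0, 1] of the lateralized amplitude effect applied to
        the midline channel Cz.
    ramp_s : float
        Length of the cosine ramp smoothing each amplitude transition, s.
        Ramps avoid the broadband splatter a step modulation would leak
        into the beta band.
    """

    fs: float = 250.0
    duration_s: float = 8.0
    cue_onset_s: float = 3.0
    task_window_s: tuple[float, float] = (0.5, 2.5)
    mu_freq: float = 10.0
    beta_freq: float = 20.0
    mu_amp: float = 1.0
    beta_amp: float = 0.5
    erd_attenuation: float = 0.5
    ers_rebound: float = 1.0
    noise_sigma: float = 0.5
    cz_mix: float = 0.25
    ramp_s: float = 0.1

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not 0 < self.erd_attenuation <= 1:
            raise ValueError(
                f"erd_attenuation must be in (0, 1], got {self.erd_attenuation}"
            )
        if self.ers_rebound < 1:
            raise ValueError(f"ers_rebound must be >= 1, got {self.ers_rebound}")
        if not 0 <= self.cz_mix <= 1:
            raise ValueError(f"cz_mix must be in [0, 1], got {self.cz_mix}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        t0, t1 = self.task_window_s
        if not t0 < t1:
            raise ValueError(f"task window must have start < end, got {t0}, {t1}")
        if self.cue_onset_s + t0 < 0 or self.cue_onset_s + t1 > self.duration_s:
            raise ValueError(
                f"task window [{self.cue_onset_s + t0}, {self.cue_onset_s + t1}] s "
                f"lies outside the epoch [0, {self.duration_s}] s"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))

    def with_(self, **changes) -> "ERDParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class EEGEpoch:
    """One labeled trial: (3, n_samples) array in channel order C3, Cz, C4."""

    channels: tuple[str, ...]
    data: np.ndarray
    fs: float
    label: str
    cue_onset_s: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2 or data.shape[0] != len(self.channels):
            raise ValueError(
                f"data shape {data.shape} inconsistent with {len(self.channels)} channels"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} not present in {self.channels}") from None


@dataclass
class EpochSet:
    """An ordered collection of epochs sharing geometry and channel order."""

    epochs: list[EEGEpoch]
    seed: int | None = None
    params: ERDParams | None = None

    def __post_init__(self) -> None:
        if self.epochs:
            first = self.epochs[0]
            for ep in self.epochs:
                if ep.fs != first.fs or ep.n_samples != first.n_samples \
                        or ep.channels != first.channels:
                    raise ValueError("all epochs must share fs, length and channels")

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def __getitem__(self, idx):
        if isinstance(idx, (list, np.ndarray)):
            return EpochSet([self.epochs[i] for i in idx], self.seed, self.params)
        return self.epochs[idx]

    @property
    def labels(self) -> np.ndarray:
        return np.array([ep.label for ep in self.epochs])

    @property
    def fs(self) -> float:
        return self.epochs[0].fs

    @property
    def channels(self) -> tuple[str, ...]:
        return self.epochs[0].channels

    def data_array(self) -> np.ndarray:
        """Stack all trials into a (n_trials, n_channels, n_samples) array."""
        return np.stack([ep.data for ep in self.epochs])


def _cosine_step(t: np.ndarray, t_edge: float, ramp_s: float) -> np.ndarray:
    """Smooth 0->1 transition centered at ``t_edge`` over ``ramp_s`` seconds."""
    if ramp_s <= 0:
        return (t >= t_edge).astype(float)
    u = np.clip((t - (t_edge - ramp_s / 2)) / ramp_s, 0.0, 1.0)
    return 0.5 * (1 - np.cos(np.pi * u))


def _amplitude_envelope(
    t: np.ndarray, params: ERDParams, task_factor: float, post_factor: float
) -> np.ndarray:
    """Piecewise envelope: 1 (baseline) -> task_factor -> post_factor."""
    t_on = params.cue_onset_s + params.task_window_s[0]
    t_off = params.cue_onset_s + params.task_window_s[1]
    env = np.ones_like(t)
    env += (task_factor - 1.0) * _cosine_step(t, t_on, params.ramp_s)
    env += (post_factor - task_factor) * _cosine_step(t, t_off, params.ramp_s)
    return env


def _pink_noise(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f power spectrum, scaled to std ``sigma``."""
    if sigma == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** -0.5  # amplitude ~ f^-1/2 -> power ~ 1/f
    pink = np.fft.irfft(spectrum * shaping, n)
    return pink * (sigma / pink.std())


def _channel_factors(label: str, params: ERDParams) -> dict[str, tuple[float, float]]:
    """Per-channel (task, post-task) amplitude factors for a given hand."""
    att, reb = params.erd_attenuation, params.ers_rebound
    contra = CONTRALATERAL[label]
    factors = {}
    for ch in CHANNELS:
        if ch == contra:
            mix = 1.0
        elif ch == "Cz":
            mix = params.cz_mix
        else:
            mix = 0.0
        factors[ch] = (1.0 - mix * (1.0 - att), 1.0 + mix * (reb - 1.0))
    return factors


def generate_epoch(label: str, params: ERDParams, seed: int) -> EEGEpoch:
    """Generate one labeled epoch with the lateralized ERD/ERS signature.

    During the task window the mu and beta oscillator amplitudes on the
    contralateral channel are multiplied by ``params.erd_attenuation``; Cz
    receives ``params.cz_mix`` of the same effect; after the task window
    amplitudes follow ``params.ers_rebound``.  Oscillator phases and the
    pink-noise background are drawn from the seeded generator.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    rng = np.random.default_rng(seed)
    t = np.arange(params.n_samples) / params.fs
    factors = _channel_factors(label, params)

    data = np.empty((len(CHANNELS), params.n_samples))
    for i, ch in enumerate(CHANNELS):
        task_f, post_f = factors[ch]
        env = _amplitude_envelope(t, params, task_f, post_f)
        phase_mu, phase_beta = rng.uniform(0, 2 * np.pi, size=2)
        signal = params.mu_amp * env * np.sin(2 * np.pi * params.mu_freq * t + phase_mu)
        signal += params.beta_amp * env * np.sin(
            2 * np.pi * params.beta_freq * t + phase_beta
        )
        signal += _pink_noise(params.n_samples, params.noise_sigma, rng)
        data[i] = signal

    return EEGEpoch(
        channels=CHANNELS, data=data, fs=params.fs,
        label=label, cue_onset_s=params.cue_onset_s,
    )


def generate_dataset(
    n_trials: int,
    class_fraction: float = 0.5,
    params: ERDParams = ERDParams(),
    seed: int = 0,
) -> EpochSet:
    """Generate a labeled dataset with deterministic per-trial seeds.

    ``round(class_fraction * n_trials)`` trials are 'left', the rest
    'right'; label order is shuffled by the master seed, and each trial's
    oscillator phases and noise use an independent child seed so the whole
    set is reproducible bit-for-bit.
    """
    if n_trials < 2:
        raise ValueError(f"n_trials must be >= 2, got {n_trials}")
    if not 0 < class_fraction < 1:
        raise ValueError(f"class_fraction must be in (0, 1), got {class_fraction}")

    n_left = int(round(class_fraction * n_trials))
    labels = np.array(["left"] * n_left + ["right"] * (n_trials - n_left))
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_trials)

    epochs = [
        generate_epoch(str(label), params, int(child_seed))
        for label, child_seed in zip(labels, child_seeds)
    ]
    return EpochSet(epochs=epochs, seed=seed, params=params)


def expected_erd_percent(params: ERDParams) -> dict[str, float]:
    """Analytic task-window ERD/ERS in percent, ignoring the noise floor.

    An amplitude factor a maps to a relative band-power change of
    100 * (a**2 - 1): the contralateral channel sits at
    ``100 * (erd_attenuation**2 - 1)``, Cz at the cz_mix-blended factor,
    and the ipsilateral channel at 0.
    """
    att = params.erd_attenuation
    cz_factor = 1.0 - params.cz_mix * (1.0 - att)
    return {
        "contralateral": 100.0 * (att**2 - 1.0),
        "ipsilateral": 0.0,
        "Cz": 100.0 * (cz_factor**2 - 1.0),
    }
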