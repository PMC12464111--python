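"""Feedback-locked EEG: synthetic epochs, Morlet TFR, theta extraction.

Epochs span -500..+1500 ms around feedback onset at 500 Hz (1001 samples,
end-inclusive). Time-frequency representations use complex Morlet wavelets
with 3 cycles (sigma_t = 3 / (2 pi f)), unit-energy normalized, over 40
linearly spaced frequencies 1-40 Hz by default. Samples where the wavelet
support extends beyond the epoch are marked invalid (NaN) rather than
silently zero-padded; a frequency whose wavelet is longer than the epoch
is flagged entirely invalid. Mean 4-8 Hz power over Fz/FCz/Cz in
100-400 ms is the midfrontal theta summary. Power is used raw by default;
a dB baseline option (-500..-200 ms) is provided.

The synthetic generator produces 1/f background noise plus a
feedback-locked ~6 Hz burst (Hanning-windowed over 100-400 ms) whose
amplitude scales with a per-participant coefficient and a correct /
incorrect condition gain, with topography maximal at FCz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import signal

MIDFRONTAL = ("Fz", "FCz", "Cz")


@dataclass
class EpochedEEG:
    """channels x trials x samples epochs (microvolts) with axis metadata."""

    data: np.ndarray
    srate: float
    tmin: float
    ch_names: tuple
    labels: pd.DataFrame  # per-trial: choice_correct, phase_nonsocial, phase_social

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be channels x trials x samples")
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError("channel axis does not match ch_names")
        if len(self.labels) != self.data.shape[1]:
            raise ValueError("labels must align with the trial axis")

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.srate

    @staticmethod
    def _base(path) -> str:
        p = str(path)
        return p[:-4] if p.endswith(".npz") else p

    def save(self, path) -> None:
        """Array container (.npz) + YAML sidecar with the metadata."""
        base = self._base(path)
        np.savez_compressed(base + ".npz", data=self.data)
        meta = {
            "srate": float(self.srate),
            "tmin": float(self.tmin),
            "ch_names": list(self.ch_names),
        }
        with open(base + ".yaml", "w") as fh:
            yaml.safe_dump(meta, fh)
        self.labels.to_csv(base + ".labels.csv", index=False)

    @classmethod
    def load(cls, path) -> "EpochedEEG":
        base = cls._base(path)
        data = np.load(base + ".npz")["data"]
        with open(base + ".yaml") as fh:
            meta = yaml.safe_load(fh)
        labels = pd.read_csv(base + ".labels.csv")
        return cls(data, meta["srate"], meta["tmin"], tuple(meta["ch_names"]), labels)


@dataclass
class TFR:
    """Power (channels x trials x freqs x samples); invalid samples NaN."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    ch_names: tuple
    valid: np.ndarray  # freqs x samples bool
    n_cycles: float


def morlet_wavelet(freq: float, srate: float, n_cycles: float = 3.0) -> np.ndarray:
    """Unit-energy complex Morlet wavelet; support truncated at 4 sigma_t."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(4.0 * sigma_t * srate))
    t = np.arange(-half, half + 1) / srate
    w = np.exp(-(t**2) / (2.0 * sigma_t**2)) * np.exp(2j * np.pi * freq * t)
    return w / np.sqrt(np.sum(np.abs(w) ** 2))


def morlet_tfr(
    epochs: EpochedEEG,
    freqs: np.ndarray | None = None,
    n_cycles: float = 3.0,
) -> TFR:
    """Morlet time-frequency power per channel/trial.

    Each trial is convolved (same-length) with the wavelet per frequency
    and the squared magnitude taken. Edge samples within half a wavelet of
    the epoch boundary are NaN; frequencies whose wavelet exceeds the epoch
    are entirely invalid (all-NaN), not an exception.
    """
    if freqs is None:
        freqs = np.linspace(1.0, 40.0, 40)
    freqs = np.asarray(freqs, dtype=float)
    n_ch, n_tr, n_samp = epochs.data.shape
    power = np.empty((n_ch, n_tr, len(freqs), n_samp), dtype=np.float32)
    valid = np.zeros((len(freqs), n_samp), dtype=bool)
    for i, f in enumerate(freqs):
        w = morlet_wavelet(f, epochs.srate, n_cycles)
        half = (len(w) - 1) // 2
        if len(w) > n_samp:
            power[:, :, i, :] = np.nan
            continue
        conv = signal.fftconvolve(epochs.data, w[np.newaxis, np.newaxis, :], mode="same", axes=-1)
        p = np.abs(conv) ** 2
        p[..., :half] = np.nan
        if half > 0:
            p[..., -half:] = np.nan
        power[:, :, i, :] = p
        valid[i, half : n_samp - half] = True
    return TFR(power, freqs, epochs.times, epochs.ch_names, valid, n_cycles)


def dB_baseline(tfr: TFR, window: tuple = (-0.5, -0.2)) -> TFR:
    """Optional dB transform relative to the trial-mean baseline window."""
    mask = (tfr.times >= window[0]) & (tfr.times <= window[1])
    base = np.nanmean(tfr.power[..., mask], axis=(1, 3), keepdims=True)
    power = 10.0 * np.log10(tfr.power / base)
    return TFR(power, tfr.freqs, tfr.times, tfr.ch_names, tfr.valid, tfr.n_cycles)


CONDITIONS = (
    "all", "correct", "incorrect",
    "stable_nonsocial", "volatile_nonsocial", "stable_social", "volatile_social",
)


def _condition_masks(labels: pd.DataFrame) -> dict:
    correct = labels["choice_correct"].to_numpy().astype(bool)
    masks = {
        "all": np.ones(len(labels), bool),
        "correct": correct,
        "incorrect": ~correct,
    }
    for source, col in (("nonsocial", "phase_nonsocial"), ("social", "phase_social")):
        for phase in ("stable", "volatile"):
            masks[f"{phase}_{source}"] = (labels[col] == phase).to_numpy()
    return masks


def extract_theta(
    tfr: TFR,
    labels: pd.DataFrame,
    window: tuple = (0.1, 0.4),
    band: tuple = (4.0, 8.0),
    electrodes: tuple = MIDFRONTAL,
) -> pd.DataFrame:
    """Mean band power over the window and electrodes, per condition.

    Returns one row per condition with the electrode-average ('midfrontal'
    when the default midfrontal triplet is used, otherwise 'mean') and one
    column per electrode. Requires the band to be fully valid within the
    window (precondition of a trustworthy summary).
    """
    fmask = (tfr.freqs >= band[0]) & (tfr.freqs <= band[1])
    tmask = (tfr.times >= window[0]) & (tfr.times <= window[1])
    if not fmask.any() or not tmask.any():
        raise ValueError("band/window select no TFR bins")
    if not tfr.valid[np.ix_(fmask, tmask)].all():
        raise ValueError("requested band is not fully valid within the window")
    missing = set(electrodes) - set(tfr.ch_names)
    if missing:
        raise ValueError(f"electrodes not present: {sorted(missing)}")
    chidx = [tfr.ch_names.index(e) for e in electrodes]
    # trials x electrodes mean band power in window
    sub = tfr.power[np.ix_(chidx, range(tfr.power.shape[1]), np.flatnonzero(fmask), np.flatnonzero(tmask))]
    per_trial = sub.mean(axis=(2, 3))  # electrodes x trials
    mean_col = "midfrontal" if tuple(electrodes) == MIDFRONTAL else "mean"
    rows = []
    for cond, mask in _condition_masks(labels).items():
        if not mask.any():
            row = dict.fromkeys(list(electrodes) + [mean_col], np.nan)
        else:
            vals = per_trial[:, mask].mean(axis=1)
            row = dict(zip(electrodes, map(float, vals)))
            row[mean_col] = float(vals.mean())
        row["condition"] = cond
        rows.append(row)
    return pd.DataFrame(rows).set_index("condition")


# ---------------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------------

@dataclass
class EEGConfig:
    srate: float = 500.0
    tmin: float = -0.5
    tmax: float = 1.5
    ch_names: tuple = ("Fz", "FCz", "Cz", "Pz", "Oz")
    noise_sd: float = 10.0          # broadband 1/f background, microvolts
    noise_exponent: float = 1.0     # power ~ 1/f^exponent
    burst_freq: float = 6.0
    burst_window: tuple = (0.1, 0.4)
    burst_amp: float = 8.0          # base amplitude, microvolts
    incorrect_gain: float = 1.5     # amplitude gain on incorrect feedback
    amp_jitter_sd: float = 0.2      # lognormal trial-to-trial amplitude jitter
    topography: dict = field(default_factory=lambda: {
        "Fz": 0.8, "FCz": 1.0, "Cz": 0.8, "Pz": 0.3, "Oz": 0.1,
    })

    @property
    def n_samples(self) -> int:
        # end-inclusive window: -0.5..1.5 s at 500 Hz -> 1001 samples
        return int(round((self.tmax - self.tmin) * self.srate)) + 1


def _one_over_f_noise(rng, shape, srate, exponent, sd):
    """Spectrally shaped Gaussian noise (power ~ 1/f^exponent), sd-scaled."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, 1.0 / srate)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    spec = rng.standard_normal(shape[:-1] + (len(freqs),)) + 1j * rng.standard_normal(
        shape[:-1] + (len(freqs),)
    )
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    x *= sd / x.std(axis=-1, keepdims=True)
    return x


def synthesize_epochs(
    config: EEGConfig,
    trial_labels: pd.DataFrame,
    rng_seed: int | np.random.Generator,
    participant_coef: float = 1.0,
) -> EpochedEEG:
    """Generate feedback-locked epochs for one participant.

    1/f background plus a Hanning-windowed burst at ``burst_freq`` over the
    burst window, amplitude = burst_amp x condition gain (incorrect >
    correct) x participant coefficient x trial jitter, with an FCz-maximal
    topography. Deterministic given the seed.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    n_tr = len(trial_labels)
    n_ch = len(config.ch_names)
    n_samp = config.n_samples
    times = config.tmin + np.arange(n_samp) / config.srate

    data = _one_over_f_noise(
        rng, (n_ch, n_tr, n_samp), config.srate, config.noise_exponent, config.noise_sd
    )

    wmask = (times >= config.burst_window[0]) & (times <= config.burst_window[1])
    burst_t = times[wmask]
    hann = np.hanning(wmask.sum())
    correct = trial_labels["choice_correct"].to_numpy().astype(bool)
    gain = np.where(correct, 1.0, config.incorrect_gain)
    jitter = np.exp(config.amp_jitter_sd * rng.standard_normal(n_tr))
    phase = rng.uniform(0, 2 * np.pi, n_tr)
    amp = config.burst_amp * participant_coef * gain * jitter  # per trial
    carrier = np.sin(
        2 * np.pi * config.burst_freq * burst_t[np.newaxis, :] + phase[:, np.newaxis]
    )
    burst = amp[:, np.newaxis] * hann[np.newaxis, :] * carrier  # trials x t
    topo = np.array([config.topography.get(ch, 0.0) for ch in config.ch_names])
    data[:, :, wmask] += topo[:, np.newaxis, np.newaxis] * burst[np.newaxis, :, :]

    return EpochedEEG(data, config.srate, config.tmin, tuple(config.ch_names), trial_labels.copy())


def bandpass_filter(
    data: np.ndarray,
    srate: float,
    low: float = 0.01,
    high: float = 40.0,
    hp_order: int = 2,
    lp_order: int = 10,
) -> np.ndarray:
    """Zero-phase band-pass along the last axis (the offline 0.01-40 Hz
    filter applied to continuous synthetic data).

    Implemented as a high-pass / low-pass cascade (separate designs are
    numerically stabler than a single band-pass with a near-DC corner);
    sosfiltfilt gives zero phase and doubles the stopband attenuation, so
    a 45 Hz probe is suppressed by > 20 dB relative to in-band tones.
    When the record is shorter than ~2 periods of the high-pass corner
    (always the case for 0.01 Hz on epoch-scale synthetic records) the
    high-pass reduces to linear detrending, since a Butterworth with a
    time constant longer than the record only contributes edge
    transients.
    """
    n = np.asarray(data).shape[-1]
    if low * n / srate < 2.0:
        out = signal.detrend(np.asarray(data, dtype=float), axis=-1)
    else:
        sos_hp = signal.butter(hp_order, low, btype="highpass", fs=srate, output="sos")
        out = signal.sosfiltfilt(sos_hp, data, axis=-1)
    sos_lp = signal.butter(lp_order, high, btype="lowpass", fs=srate, output="sos")
    return signal.sosfiltfilt(sos_lp, out, axis=-1)


def rereference_linked_mastoids(
    data: np.ndarray, ch_names: tuple, mastoids: tuple = ("M1", "M2")
) -> np.ndarray:
    """Subtract the average of the mastoid channels from every channel."""
    idx = [ch_names.index(m) for m in mastoids if m in ch_names]
    if not idx:
        raise ValueError("no mastoid channels present")
    return data - data[idx].mean(axis=0, keepdims=True)
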