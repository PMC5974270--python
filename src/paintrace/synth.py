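"""Synthetic session generator for laser-evoked pain recordings.

Emulates the statistical structure of acute thermal pain experiments in rat
anterior cingulate cortex: multi-channel LFP with a 1/f^alpha (pink)
background, stimulus-locked event-related synchronization (ERS) in
configurable frequency bands whose magnitude scales with laser intensity and
is amplified in the chronic-pain (CFA) condition, sparse Poisson spiking with
a minority of stimulus-modulated units, and intensity-dependent paw-withdrawal
latencies capped at the 5-s stimulus window.

All randomness is driven by :class:`numpy.random.SeedSequence` spawning, so a
``(config, seed)`` pair reproduces a session bit for bit.
"""

from __future__ import annotations

import enum
import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.fft import rfft, irfft, rfftfreq

__all__ = [
    "StimulusIntensity",
    "SynthConfig",
    "Trial",
    "Session",
    "make_session",
    "synth_lfp_trial",
    "synth_spikes",
    "synth_withdrawal",
    "n_modulated_units",
    "session_checksum",
]


class StimulusIntensity(enum.Enum):
    """Laser stimulus class: non-noxious, low-noxious, high-noxious.

    Ordered by laser power (NS < LS < HS); the label-to-power mapping is
    fixed: 50, 150 and 250 mW respectively.
    """

    NS = 50
    LS = 150
    HS = 250

    @property
    def laser_power(self) -> int:
        """Calibrated laser power in milliwatts."""
        return self.value

    @property
    def label(self) -> str:
        return self.name

    def __lt__(self, other: "StimulusIntensity") -> bool:
        return self.value < other.value

    @classmethod
    def parse(cls, x) -> "StimulusIntensity":
        if isinstance(x, cls):
            return x
        try:
            return cls[str(x).upper()]
        except KeyError:
            raise ValueError(f"unknown stimulus intensity {x!r}") from None


CONDITIONS = ("naive", "CFA")

# Rate multiplier of the stimulus-locked modulation by intensity: non-noxious
# stimuli leave even "pain-modulated" units at baseline.
INTENSITY_RATE_FACTOR = {"NS": 0.0, "LS": 0.6, "HS": 1.0}


def _default_ers_gain() -> dict:
    # Band-power multipliers during the stimulus epoch. Nociceptive ERS is
    # carried by theta and high gamma, scaling with laser intensity; the
    # remaining bands stay at their baseline level.
    return {
        "theta": {"NS": 1.0, "LS": 2.5, "HS": 5.0},
        "high_gamma": {"NS": 1.0, "LS": 2.0, "HS": 4.0},
    }


def _default_latency_params() -> dict:
    # Gamma(shape, scale) per noxious intensity, truncated to (0, 5] at draw
    # time. Means ~3 s (LS) and ~2 s (HS): hotter lasers evoke earlier
    # withdrawal.
    return {"LS": (9.0, 1.0 / 3.0), "HS": (9.0, 2.0 / 9.0)}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic session generator.

    Attributes
    ----------
    n_trials_per_class:
        Trials per stimulus class; a session holds twice this many.
    channels:
        LFP channels (one per tetrode).
    fs:
        Sampling rate, samples/s.
    t_range:
        Trial window in seconds around laser onset at 0; half-open grid,
        sample k sits at ``t_range[0] + k / fs``.
    background_exponent:
        Slope alpha of the 1/f^alpha background spectrum.
    background_std:
        Per-channel background standard deviation, microvolts.
    shared_fraction:
        Fraction of background variance carried by a latent component common
        to all channels (the rest is independent channel noise).
    ers_gain:
        ``band -> intensity label -> power multiplier`` applied to that band
        during the stimulus epoch. Bands absent from the map stay at gain 1.
    cfa_gain_multiplier:
        Chronic-pain amplification of the ERS excess, applied to noxious
        (LS/HS) gains: effective gain ``1 + m * (g - 1)``.
    ers_onset_delay:
        Seconds after laser onset before the ERS begins (default 0).
    ramp_s:
        Raised-cosine ramp length at the ERS epoch edges, seconds.
    n_units / frac_modulated / base_rate / modulated_rate_gain:
        Poisson spiking model: unit count, fraction of stimulus-modulated
        units, baseline rate (spikes/s), and epoch rate multiplier for
        modulated units at full (HS) intensity.
    latency_params:
        ``intensity label -> (gamma shape, gamma scale)`` for the withdrawal
        latency; NS never withdraws.
    """

    n_trials_per_class: int = 30
    channels: int = 8
    fs: float = 1000.0
    t_range: tuple = (-5.0, 5.0)
    background_exponent: float = 1.0
    background_std: float = 50.0
    shared_fraction: float = 0.6
    ers_gain: dict = field(default_factory=_default_ers_gain)
    cfa_gain_multiplier: float = 1.5
    ers_onset_delay: float = 0.0
    ramp_s: float = 0.05
    n_units: int = 16
    frac_modulated: float = 0.25
    base_rate: float = 5.0
    modulated_rate_gain: float = 3.0
    latency_params: dict = field(default_factory=_default_latency_params)
    seed: int | None = None

    def __post_init__(self):
        if self.n_trials_per_class < 15:
            raise ValueError("n_trials_per_class must be >= 15")
        if self.channels < 1 or self.n_units < 0:
            raise ValueError("channels must be >= 1 and n_units >= 0")
        if not 0.0 <= self.frac_modulated <= 1.0:
            raise ValueError("frac_modulated must lie in [0, 1]")
        if self.base_rate < 0 or self.modulated_rate_gain < 0:
            raise ValueError("rates and rate gains must be non-negative")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")
        for band, per_int in self.ers_gain.items():
            for lab, g in per_int.items():
                if g < 0:
                    raise ValueError(f"ers_gain[{band}][{lab}] must be >= 0")
        n = (self.t_range[1] - self.t_range[0]) * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * duration must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round((self.t_range[1] - self.t_range[0]) * self.fs))

    def time_grid(self) -> np.ndarray:
        """Half-open sample-time grid [t0, t1)."""
        return self.t_range[0] + np.arange(self.n_samples) / self.fs


@dataclass
class Trial:
    """One stimulation event.

    ``lfp`` is channels x samples on the config time grid (time 0 = laser
    onset); ``spikes`` holds per-unit spike times in seconds relative to
    onset; ``withdrawal_latency`` is in (0, 5] seconds or None when the paw
    was not withdrawn (always the case for NS). ``denoised`` is filled by the
    preprocessing stage.
    """

    trial_id: int
    intensity: StimulusIntensity
    condition: str
    lfp: np.ndarray
    spikes: list
    withdrawal_latency: float | None
    denoised: np.ndarray | None = None

    @property
    def epoch_end(self) -> float:
        """End of the stimulus epoch: withdrawal or the 5-s cap."""
        return 5.0 if self.withdrawal_latency is None else self.withdrawal_latency


@dataclass
class Session:
    """Ordered trial collection for one recording (two stimulus classes)."""

    trials: list
    class_pair: tuple
    condition: str
    config: SynthConfig
    seed: int

    def __post_init__(self):
        labels = {t.intensity.label for t in self.trials}
        if labels != {i.label for i in self.class_pair}:
            raise ValueError("session trials do not match the class pair")

    def labels(self) -> np.ndarray:
        return np.array([t.intensity.label for t in self.trials])

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def _parse_pair(class_pair) -> tuple:
    if isinstance(class_pair, str):
        parts = class_pair.replace("_", "-").split("-")
    else:
        parts = list(class_pair)
    if len(parts) != 2:
        raise ValueError(f"class pair must name two intensities, got {class_pair!r}")
    a, b = (StimulusIntensity.parse(p) for p in parts)
    if a == b:
        raise ValueError("class pair must name two distinct intensities")
    return (a, b) if a < b else (b, a)


def _pink_weights(config: SynthConfig) -> np.ndarray:
    """rFFT amplitude weights for the 1/f^alpha background.

    The divergence at DC is tamed by flattening the spectrum below 1 Hz,
    a standard pinking floor; DC itself is zeroed.
    """
    f = rfftfreq(config.n_samples, 1.0 / config.fs)
    w = np.zeros_like(f)
    floor = max(1.0, f[1])
    w[1:] = np.maximum(f[1:], floor) ** (-config.background_exponent / 2.0)
    return w


def _colored_noise(rng: np.random.Generator, weights: np.ndarray, n: int) -> np.ndarray:
    """Unit-variance Gaussian noise with rFFT amplitude profile ``weights``."""
    x = irfft(rfft(rng.standard_normal(n)) * weights, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_frac(config: SynthConfig, lo: float, hi: float) -> float:
    """Fraction of background variance inside [lo, hi) Hz."""
    f = rfftfreq(config.n_samples, 1.0 / config.fs)
    w2 = _pink_weights(config) ** 2
    tot = w2.sum()
    return float(w2[(f >= lo) & (f < hi)].sum() / tot)


def _band_edges(band: str):
    # Edges shared with the spectral module; imported lazily to keep synth
    # importable on its own.
    from .spectral import BANDS

    b = BANDS[band]
    return b.lo, b.hi


def effective_gain(config: SynthConfig, band: str, intensity: StimulusIntensity, condition: str) -> float:
    """Band power multiplier during the epoch, after CFA amplification.

    CFA scales the ERS *excess* (g - 1) of noxious stimuli, so bands whose
    gain is 1 stay null in both conditions.
    """
    g = float(config.ers_gain.get(band, {}).get(intensity.label, 1.0))
    if condition == "CFA" and intensity is not StimulusIntensity.NS:
        g = 1.0 + config.cfa_gain_multiplier * (g - 1.0)
    return g


def _epoch_envelope(config: SynthConfig, t_end: float) -> np.ndarray:
    """0/1 envelope over the grid for the ERS epoch, with cosine ramps."""
    t = config.time_grid()
    t0 = config.ers_onset_delay
    env = np.zeros_like(t)
    core = (t >= t0) & (t < t_end)
    env[core] = 1.0
    r = config.ramp_s
    if r > 0:
        up = (t >= t0) & (t < t0 + r)
        env[up] = 0.5 * (1.0 - np.cos(np.pi * (t[up] - t0) / r))
        dn = (t >= t_end - r) & (t < t_end)
        env[dn] = 0.5 * (1.0 - np.cos(np.pi * (t_end - t[dn]) / r))
    return env


def synth_lfp_trial(
    intensity,
    condition: str,
    config: SynthConfig,
    seed,
    epoch_end: float | None = None,
) -> np.ndarray:
    """Simulate one trial's channels x samples LFP matrix (microvolts).

    Background: pink noise with a latent component shared across channels
    plus independent channel noise. During ``[ers_onset_delay, epoch_end)``
    band-limited Gaussian noise is added to the shared component so that each
    configured band's power is multiplied by its effective gain; the baseline
    half of the trial is untouched.
    """
    intensity = StimulusIntensity.parse(intensity)
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    rng = np.random.default_rng(seed)
    n = config.n_samples
    w = _pink_weights(config)
    sigma = config.background_std
    rho = config.shared_fraction

    shared = _colored_noise(rng, w, n)
    if epoch_end is None:
        epoch_end = 5.0
    ers = np.zeros(n)
    env = None
    f = rfftfreq(n, 1.0 / config.fs)
    for band in config.ers_gain:
        g = effective_gain(config, band, intensity, condition)
        if g == 1.0:
            continue
        lo, hi = _band_edges(band)
        mask = ((f >= lo) & (f < hi)).astype(float)
        comp = _colored_noise(rng, mask, n)
        target_var = (g - 1.0) * sigma**2 * _band_frac(config, lo, hi)
        if env is None:
            env = _epoch_envelope(config, epoch_end)
        ers += np.sqrt(max(target_var, 0.0)) * comp * env

    lfp = np.empty((config.channels, n))
    for c in range(config.channels):
        indep = _colored_noise(rng, w, n)
        lfp[c] = sigma * (np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep) + ers
    return lfp


def n_modulated_units(config: SynthConfig) -> int:
    """Number of stimulus-modulated units: round-half-up of the fraction."""
    return int(np.floor(config.frac_modulated * config.n_units + 0.5))


def synth_spikes(
    intensity,
    condition: str,
    config: SynthConfig,
    seed,
    epoch_end: float = 5.0,
    modulated_units: np.ndarray | None = None,
) -> list:
    """Simulate per-unit spike-time lists for one trial.

    Each unit is a homogeneous Poisson process at ``base_rate``; units in the
    modulated subset switch during the stimulus epoch to
    ``base_rate * (1 + (modulated_rate_gain - 1) * intensity_factor)`` with
    intensity factors 0 (NS), 0.6 (LS), 1 (HS). The modulated subset is fixed
    per session and passed in by :func:`make_session`; when absent it is
    drawn deterministically from the seed.
    """
    intensity = StimulusIntensity.parse(intensity)
    if config.n_units < 1:
        raise ValueError("n_units must be >= 1")
    rng = np.random.default_rng(seed)
    if modulated_units is None:
        k = n_modulated_units(config)
        modulated_units = rng.choice(config.n_units, size=k, replace=False)
    modulated = set(int(u) for u in modulated_units)

    t0, t1 = config.t_range
    factor = INTENSITY_RATE_FACTOR[intensity.label]
    gain = 1.0 + (config.modulated_rate_gain - 1.0) * factor
    e0, e1 = config.ers_onset_delay, min(epoch_end, t1)

    spikes = []
    for u in range(config.n_units):
        rate_epoch = config.base_rate * (gain if u in modulated else 1.0)
        segs = [(t0, e0, config.base_rate), (e0, e1, rate_epoch), (e1, t1, config.base_rate)]
        times = []
        for a, b, r in segs:
            if b <= a or r <= 0:
                continue
            cnt = rng.poisson(r * (b - a))
            times.append(rng.uniform(a, b, size=cnt))
        st = np.sort(np.concatenate(times)) if times else np.empty(0)
        spikes.append(st)
    return spikes


def synth_withdrawal(intensity, config: SynthConfig, seed) -> float | None:
    """Draw a withdrawal latency, or None for non-noxious stimuli.

    Noxious latencies follow a per-intensity gamma distribution truncated to
    (0, 5] by rejection; under the defaults HS withdraws earlier than LS.
    """
    intensity = StimulusIntensity.parse(intensity)
    if intensity is StimulusIntensity.NS:
        return None
    if intensity.label not in config.latency_params:
        raise ValueError(f"no latency parameters for {intensity.label}")
    shape, scale = config.latency_params[intensity.label]
    rng = np.random.default_rng(seed)
    for _ in range(10_000):
        x = rng.gamma(shape, scale)
        if 0.0 < x <= 5.0:
            return float(x)
    raise RuntimeError("withdrawal-latency rejection sampling failed to converge")


def make_session(config: SynthConfig, class_pair, condition: str = "naive", seed: int = 0) -> Session:
    """Generate a balanced, randomly interleaved two-class session.

    The two lasers are interleaved at random (a uniformly drawn permutation
    of the balanced label sequence), mirroring randomized double-laser
    delivery. Deterministic given ``(config, seed)``.
    """
    pair = _parse_pair(class_pair)
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if config.n_trials_per_class <= 0:
        raise ValueError("n_trials_per_class must be positive")

    ss = np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(ss.spawn(1)[0])
    n = config.n_trials_per_class
    labels = np.array([0] * n + [1] * n)
    order_rng.shuffle(labels)

    k = n_modulated_units(config)
    modulated = order_rng.choice(config.n_units, size=k, replace=False) if k else np.empty(0, int)

    children = ss.spawn(2 * n)
    trials = []
    for i, lab in enumerate(labels):
        intensity = pair[lab]
        sub = children[i].spawn(3)
        latency = synth_withdrawal(intensity, config, sub[0])
        epoch_end = 5.0 if latency is None else latency
        lfp = synth_lfp_trial(intensity, condition, config, sub[1], epoch_end=epoch_end)
        spikes = synth_spikes(intensity, condition, config, sub[2], epoch_end=epoch_end, modulated_units=modulated)
        trials.append(
            Trial(
                trial_id=i,
                intensity=intensity,
                condition=condition,
                lfp=lfp,
                spikes=spikes,
                withdrawal_latency=latency,
            )
        )
    return Session(trials=trials, class_pair=pair, condition=condition, config=config, seed=seed)


def session_checksum(session: Session) -> str:
    """SHA-256 over all trial data and metadata; bitwise determinism probe."""
    import json

    h = hashlib.sha256()
    cfg = asdict(session.config)
    h.update(json.dumps(cfg, sort_keys=True, default=list).encode())
    h.update(f"{session.condition}|{[i.label for i in session.class_pair]}|{session.seed}".encode())
    for t in session.trials:
        h.update(f"{t.trial_id}|{t.intensity.label}|{t.condition}|{t.withdrawal_latency}".encode())
        h.update(np.ascontiguousarray(t.lfp).tobytes())
        for st in t.spikes:
            h.update(np.ascontiguousarray(st).tobytes())
    return h.hexdigest()
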