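"""Multitaper spectral estimation and baseline-referenced band power.

Implements the multitaper (Slepian/DPSS) spectrum and spectrogram with the
standard [TW, K] parameterization (TW = 3, K = 2*TW - 1 = 5 by default),
band-power summation over the canonical LFP bands, and the event-related
synchronization Z-score of response-epoch band power against the pre-stimulus
baseline distribution across trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss as _dpss

__all__ = [
    "BandDefinition",
    "BANDS",
    "TaperSet",
    "SpectralEstimate",
    "BandPowerZ",
    "dpss_tapers",
    "multitaper_psd",
    "multitaper_spectrogram",
    "band_power",
    "zscore_band_power",
    "zscore_from_powers",
]


@dataclass(frozen=True)
class BandDefinition:
    """Frequency band, half-open [lo, hi) so shared edges are counted once."""

    name: str
    lo: float
    hi: float


#: Canonical LFP bands; together they tile [4, 100) Hz exactly once.
BANDS = {
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 15.0),
    "beta": BandDefinition("beta", 15.0, 30.0),
    "low_gamma": BandDefinition("low_gamma", 30.0, 60.0),
    "high_gamma": BandDefinition("high_gamma", 60.0, 100.0),
}

BAND_ORDER = ("theta", "alpha", "beta", "low_gamma", "high_gamma")


def resolve_band(band) -> BandDefinition:
    if isinstance(band, BandDefinition):
        return band
    try:
        return BANDS[band]
    except KeyError:
        raise ValueError(f"unknown band {band!r}; known: {sorted(BANDS)}") from None


@dataclass(frozen=True)
class TaperSet:
    """First K discrete prolate spheroidal sequences of length N.

    Each taper has unit L2 norm and the set is orthonormal; tapers are
    ordered by spectral concentration within [-W, W], W = TW / (N / fs).
    """

    N: int
    TW: float
    K: int
    tapers: np.ndarray


def dpss_tapers(N: int, TW: float = 3.0, K: int | None = None) -> TaperSet:
    """Slepian tapers for multitaper estimation.

    K defaults to 2*TW - 1. Requesting K > round(2*TW) yields tapers that are
    poorly concentrated in band; this is flagged with a warning rather than
    an error.
    """
    if K is None:
        K = int(round(2 * TW - 1))
    if not (N >= K >= 1):
        raise ValueError(f"need N >= K >= 1, got N={N}, K={K}")
    if TW <= 0:
        raise ValueError("TW must be positive")
    if K > round(2 * TW):
        warnings.warn(
            f"K={K} exceeds 2*TW={2 * TW:g}; trailing tapers are ill-concentrated",
            stacklevel=2,
        )
    tapers = np.atleast_2d(_dpss(N, TW, Kmax=K))
    tapers = tapers / np.linalg.norm(tapers, axis=1, keepdims=True)
    return TaperSet(N=N, TW=float(TW), K=K, tapers=tapers)


@dataclass
class SpectralEstimate:
    """Non-negative power on a frequency (and optionally time) grid.

    ``power`` is (freqs,) for a spectrum or (times, freqs) for a spectrogram;
    ``times`` holds window centers in seconds relative to the trace start.
    """

    freqs: np.ndarray
    power: np.ndarray
    times: np.ndarray | None = None
    params: dict | None = None


def _mt_psd_matrix(segments: np.ndarray, fs: float, taper_set: TaperSet) -> np.ndarray:
    """Multitaper PSD of each row of ``segments`` (…, N) -> (…, N//2+1)."""
    tapered = segments[..., np.newaxis, :] * taper_set.tapers
    spec = np.abs(rfft(tapered, axis=-1)) ** 2
    # One-sided density: double interior bins, divide by fs.
    psd = spec.mean(axis=-2) / fs
    psd[..., 1:] *= 2.0
    if segments.shape[-1] % 2 == 0:
        psd[..., -1] /= 2.0
    return psd


def multitaper_psd(trace: np.ndarray, fs: float, taper_set: TaperSet) -> SpectralEstimate:
    """Average of the K eigenspectra of a single trace."""
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ValueError("trace must be one-dimensional")
    if trace.size != taper_set.N:
        raise ValueError(f"trace length {trace.size} != taper length {taper_set.N}")
    psd = _mt_psd_matrix(trace, fs, taper_set)
    freqs = rfftfreq(taper_set.N, 1.0 / fs)
    return SpectralEstimate(
        freqs=freqs,
        power=psd,
        params={"TW": taper_set.TW, "K": taper_set.K, "N": taper_set.N, "fs": fs},
    )


def multitaper_spectrogram(
    trace: np.ndarray,
    fs: float,
    window_s: float,
    step_s: float,
    TW: float = 3.0,
    K: int | None = None,
) -> SpectralEstimate:
    """Sliding-window multitaper PSD.

    Produces ``floor((n_samples - window) / step) + 1`` columns; times are
    window centers relative to the trace start.
    """
    trace = np.asarray(trace, dtype=float)
    w = int(round(window_s * fs))
    s = int(round(step_s * fs))
    if w > trace.size:
        raise ValueError("window longer than trace")
    if s < 1:
        raise ValueError("step must be at least one sample")
    ts = dpss_tapers(w, TW, K)
    n_t = (trace.size - w) // s + 1
    starts = np.arange(n_t) * s
    segments = np.stack([trace[a : a + w] for a in starts])
    psd = _mt_psd_matrix(segments, fs, ts)
    freqs = rfftfreq(w, 1.0 / fs)
    times = (starts + w / 2.0) / fs
    return SpectralEstimate(
        freqs=freqs,
        power=psd,
        times=times,
        params={"TW": ts.TW, "K": ts.K, "window_s": window_s, "step_s": step_s, "fs": fs},
    )


def band_power(est: SpectralEstimate, band) -> float | np.ndarray:
    """Sum of estimated power over the band's frequency bins [lo, hi)."""
    band = resolve_band(band)
    sel = (est.freqs >= band.lo) & (est.freqs < band.hi)
    if not sel.any():
        raise ValueError(f"band {band.name} contains no frequency bins")
    out = est.power[..., sel].sum(axis=-1)
    return float(out) if np.ndim(out) == 0 else out


def zscore_from_powers(response: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Z of per-trial response powers against the cross-trial baseline.

    z_i = (response_i - mean(baseline)) / sd(baseline); positive z means a
    power increase relative to the pre-stimulus period.
    """
    baseline = np.asarray(baseline, dtype=float)
    if baseline.size < 2:
        raise ValueError("need >= 2 trials to estimate baseline dispersion")
    sd = baseline.std(ddof=1)
    if sd == 0:
        raise ValueError("zero baseline dispersion; Z-score undefined")
    return (np.asarray(response, dtype=float) - baseline.mean()) / sd


@dataclass
class BandPowerZ:
    """Per-trial band power in both epochs plus the ERS Z-score."""

    band: BandDefinition
    response_power: np.ndarray
    baseline_power: np.ndarray
    z: np.ndarray


def _epoch_slice(config, epoch: tuple) -> slice:
    t0 = config.t_range[0]
    a = int(round((epoch[0] - t0) * config.fs))
    b = int(round((epoch[1] - t0) * config.fs))
    if a < 0 or b > config.n_samples or b <= a:
        raise ValueError(f"epoch {epoch} outside the trial time range")
    return slice(a, b)


def zscore_band_power(
    session,
    band,
    response_epoch: tuple = (0.0, 5.0),
    baseline_epoch: tuple = (-5.0, 0.0),
    TW: float = 3.0,
    K: int | None = None,
) -> BandPowerZ:
    """ERS Z-score of response-epoch band power for every trial of a session.

    Band power is the multitaper PSD summed over the band on each epoch's
    samples (epochs half-open on the trial grid); dispersion is taken across
    trials of the baseline epoch. Uses the trial's denoised single-channel
    trace, computing it on the fly where the preprocessing stage has not
    run yet.
    """
    from .preprocess import denoise_trial

    band = resolve_band(band)
    if len(session.trials) < 2:
        raise ValueError("need >= 2 trials")
    cfg = session.config
    rs, bs = _epoch_slice(cfg, response_epoch), _epoch_slice(cfg, baseline_epoch)
    ts_r = dpss_tapers(rs.stop - rs.start, TW, K)
    ts_b = ts_r if (bs.stop - bs.start) == (rs.stop - rs.start) else dpss_tapers(bs.stop - bs.start, TW, K)

    resp, base = [], []
    for t in session.trials:
        trace = t.denoised if t.denoised is not None else denoise_trial(t.lfp)
        resp.append(band_power(multitaper_psd(trace[rs], cfg.fs, ts_r), band))
        base.append(band_power(multitaper_psd(trace[bs], cfg.fs, ts_b), band))
    resp, base = np.array(resp), np.array(base)
    return BandPowerZ(band=band, response_power=resp, baseline_power=base, z=zscore_from_powers(resp, base))
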