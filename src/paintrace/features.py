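"""Cumulative per-time-bin feature construction for decoding.

Features are evaluated on a 50-ms grid over (0, 5] after laser onset. Spike
features are per-unit counts in consecutive 50-ms bins; LFP features are
multitaper band-power sums over the trailing 1-s window ending at each step.
By default both accumulate: the design matrix at bin k concatenates the
per-step features of bins 1..k (bin-major), so every bin's columns are a
prefix of the next bin's — the dimensionality grows from d to 100*d across
the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from numpy.fft import rfftfreq

from .preprocess import denoise_trial
from .spectral import BAND_ORDER, _mt_psd_matrix, dpss_tapers, resolve_band

__all__ = [
    "FeatureSeries",
    "cumulative_spike_features",
    "lfp_band_features",
    "combine_features",
    "session_labels",
]


@dataclass
class FeatureSeries:
    """Per-time-bin design matrices with the prefix property.

    ``step_features`` is trials x n_bins x d_step; ``matrix_at(k)`` returns
    the trials x (k * d_step) accumulated design matrix for 1-based bin k
    (or the per-step matrix when ``accumulate`` is off). ``times`` holds the
    bin-end seconds.
    """

    times: np.ndarray
    step_features: np.ndarray
    modality: str
    feature_names: list
    accumulate: bool = True
    labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.step_features.ndim != 3:
            raise ValueError("step_features must be trials x bins x d_step")
        if self.step_features.shape[1] != self.times.size:
            raise ValueError("times and step_features bin counts differ")

    @property
    def n_trials(self) -> int:
        return self.step_features.shape[0]

    @property
    def n_bins(self) -> int:
        return self.step_features.shape[1]

    @property
    def d_step(self) -> int:
        return self.step_features.shape[2]

    def matrix_at(self, k: int) -> np.ndarray:
        """Design matrix at bin k (1-based)."""
        if not 1 <= k <= self.n_bins:
            raise ValueError(f"bin {k} outside 1..{self.n_bins}")
        if self.accumulate:
            return self.step_features[:, :k, :].reshape(self.n_trials, k * self.d_step)
        return self.step_features[:, k - 1, :]

    @property
    def final_matrix(self) -> np.ndarray:
        return self.matrix_at(self.n_bins)

    def names_at(self, k: int) -> list:
        if not self.accumulate:
            return [f"{n}@bin{k}" for n in self.feature_names]
        return [f"{n}@bin{j}" for j in range(1, k + 1) for n in self.feature_names]


def session_labels(session) -> np.ndarray:
    """Per-trial intensity labels, the decoding target."""
    return session.labels()


def _bin_ends(bin_s: float, horizon_s: float) -> np.ndarray:
    n = horizon_s / bin_s
    if abs(n - round(n)) > 1e-9:
        raise ValueError("bin size must divide the horizon")
    return bin_s * np.arange(1, int(round(n)) + 1)


def cumulative_spike_features(session, bin_s: float = 0.05, horizon_s: float = 5.0) -> FeatureSeries:
    """Per-unit spike counts in consecutive bins from laser onset.

    Bin membership is half-open (start, end]: a spike exactly at time 0
    belongs to the baseline, one exactly at a bin edge to the earlier bin.
    The accumulated design matrix at the final bin has dimension
    ``n_bins * n_units``.
    """
    ends = _bin_ends(bin_s, horizon_s)
    n_bins = ends.size
    n_units = len(session.trials[0].spikes)
    if n_units == 0:
        raise ValueError("session has no units")
    edges = np.concatenate([[0.0], ends])

    X = np.zeros((len(session.trials), n_bins, n_units))
    for i, trial in enumerate(session.trials):
        for u, st in enumerate(trial.spikes):
            st = np.asarray(st)
            idx = np.searchsorted(edges, st, side="left") - 1
            idx = idx[(idx >= 0) & (idx < n_bins)]
            if idx.size:
                X[i, :, u] = np.bincount(idx, minlength=n_bins)
    names = [f"unit{u}" for u in range(n_units)]
    return FeatureSeries(
        times=ends,
        step_features=X,
        modality="spike",
        feature_names=names,
        labels=session_labels(session),
        meta={"bin_s": bin_s, "horizon_s": horizon_s},
    )


def lfp_band_features(
    session,
    bands=BAND_ORDER,
    window_s: float = 1.0,
    step_s: float = 0.05,
    horizon_s: float = 5.0,
    TW: float = 3.0,
    K: int | None = None,
    accumulate: bool = True,
) -> FeatureSeries:
    """Trailing-window multitaper band powers on the 50-ms step grid.

    At step time t the window covers [t - window_s, t): steps earlier than
    one window length reach into the pre-stimulus baseline, keeping the grid
    aligned with the spike bins from time 0. With several bands the per-step
    powers are concatenated (the "all frequency" feature); accumulation
    across steps mirrors the spike counts.
    """
    bands = [resolve_band(b) for b in (bands if not isinstance(bands, str) else [bands])]
    cfg = session.config
    ends = _bin_ends(step_s, horizon_s)
    w = int(round(window_s * cfg.fs))
    taper_set = dpss_tapers(w, TW, K)
    t0 = cfg.t_range[0]
    if ends[0] - window_s < t0 - 1e-9:
        raise ValueError("trailing window extends before the trial start")

    starts = np.round((ends - window_s - t0) * cfg.fs).astype(int)
    X = np.empty((len(session.trials), ends.size, len(bands)))
    for i, trial in enumerate(session.trials):
        trace = trial.denoised if trial.denoised is not None else denoise_trial(trial.lfp)
        segs = np.stack([trace[a : a + w] for a in starts])
        # One vectorized multitaper pass over all windows of the trial.
        psd = _mt_psd_matrix(segs, cfg.fs, taper_set)
        freqs = rfftfreq(w, 1.0 / cfg.fs)
        for j, b in enumerate(bands):
            sel = (freqs >= b.lo) & (freqs < b.hi)
            X[i, :, j] = psd[:, sel].sum(axis=1)

    modality = "lfp_band" if len(bands) == 1 else "lfp_all"
    return FeatureSeries(
        times=ends,
        step_features=X,
        modality=modality,
        feature_names=[b.name for b in bands],
        accumulate=accumulate,
        labels=session_labels(session),
        meta={"window_s": window_s, "step_s": step_s, "TW": TW, "K": taper_set.K},
    )


def combine_features(a: FeatureSeries, b: FeatureSeries) -> FeatureSeries:
    """Column-wise per-bin concatenation of two feature series."""
    if a.n_trials != b.n_trials:
        raise ValueError("trial sets differ")
    if a.times.size != b.times.size or not np.allclose(a.times, b.times):
        raise ValueError("time grids differ")
    if a.accumulate != b.accumulate:
        raise ValueError("accumulation modes differ")
    if a.labels is not None and b.labels is not None and not np.array_equal(a.labels, b.labels):
        raise ValueError("trial labels differ")
    return FeatureSeries(
        times=a.times.copy(),
        step_features=np.concatenate([a.step_features, b.step_features], axis=2),
        modality="combined",
        feature_names=list(a.feature_names) + list(b.feature_names),
        accumulate=a.accumulate,
        labels=a.labels if a.labels is not None else b.labels,
        meta={"a": a.modality, "b": b.modality},
    )
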