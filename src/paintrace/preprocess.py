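"""LFP preprocessing: detrend, artifact-channel rejection, PCA denoising.

Reduces each trial's multi-channel LFP to one denoised trace: channels are
linearly detrended, channels whose total power is a robust outlier across the
array are dropped, and the remainder is projected onto the first principal
axis of the channel covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend as _sp_detrend

__all__ = [
    "ChannelMask",
    "UnusableTrialError",
    "detrend",
    "reject_artifact_channels",
    "pca_first_component",
    "denoise_trial",
    "denoise_session",
]

# Consistency constant relating MAD to the SD of a Gaussian.
_MAD_SCALE = 0.6744897501960817


class UnusableTrialError(ValueError):
    """Raised when artifact rejection leaves no usable channel."""


@dataclass
class ChannelMask:
    """Per-channel keep flags with a reason code for each rejected channel."""

    kept: np.ndarray
    reason: dict

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())


def detrend(trace: np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend (and hence the mean)."""
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or trace.size < 2:
        raise ValueError("detrend needs a 1-D trace with at least 2 samples")
    return _sp_detrend(trace, type="linear")


def reject_artifact_channels(lfp: np.ndarray, robust_z_threshold: float = 3.0) -> ChannelMask:
    """Flag channels whose log total power is a robust outlier.

    The statistic is the robust Z of each channel's log mean-square power
    against the median/MAD across channels; |Z| above the threshold rejects
    the channel (catching both saturated and dead channels). Zero MAD (all
    channels alike) keeps everything. Scale-equivariant: a common gain on all
    channels shifts every log power equally and changes no decision.
    """
    lfp = np.asarray(lfp, dtype=float)
    if lfp.ndim != 2 or lfp.shape[0] < 2:
        raise ValueError("need a channels x samples matrix with >= 2 channels")
    logp = np.log(np.mean(lfp**2, axis=1) + np.finfo(float).tiny)
    med = np.median(logp)
    mad = np.median(np.abs(logp - med))
    kept = np.ones(lfp.shape[0], dtype=bool)
    reason: dict = {}
    if mad > 0:
        z = _MAD_SCALE * (logp - med) / mad
        for c in np.flatnonzero(np.abs(z) > robust_z_threshold):
            kept[c] = False
            reason[int(c)] = "power_outlier_high" if z[c] > 0 else "power_outlier_low"
    if not kept.any():
        raise UnusableTrialError("artifact rejection removed every channel")
    return ChannelMask(kept=kept, reason=reason)


def pca_first_component(lfp: np.ndarray) -> np.ndarray:
    """Project the channel ensemble onto its first principal axis.

    Expects detrended channels. The eigen-sign ambiguity is resolved so the
    output correlates non-negatively with the across-channel mean; a single
    channel passes through unchanged.
    """
    lfp = np.atleast_2d(np.asarray(lfp, dtype=float))
    if lfp.shape[0] == 1:
        return lfp[0].copy()
    cov = lfp @ lfp.T / (lfp.shape[1] - 1)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, -1]
    out = v @ lfp
    if np.dot(out, lfp.mean(axis=0)) < 0:
        out = -out
    return out


def denoise_trial(lfp: np.ndarray, robust_z_threshold: float = 3.0) -> np.ndarray:
    """Full per-trial chain: detrend -> reject channels -> first PC."""
    lfp = np.atleast_2d(np.asarray(lfp, dtype=float))
    det = np.stack([detrend(ch) for ch in lfp])
    if det.shape[0] >= 2:
        mask = reject_artifact_channels(det, robust_z_threshold)
        det = det[mask.kept]
    return pca_first_component(det)


def denoise_session(session, robust_z_threshold: float = 3.0) -> list:
    """Fill ``trial.denoised`` for every trial; returns the channel masks."""
    masks = []
    for t in session.trials:
        lfp = np.atleast_2d(np.asarray(t.lfp, dtype=float))
        det = np.stack([detrend(ch) for ch in lfp])
        if det.shape[0] >= 2:
            mask = reject_artifact_channels(det, robust_z_threshold)
            det = det[mask.kept]
        else:
            mask = ChannelMask(kept=np.ones(1, dtype=bool), reason={})
        t.denoised = pca_first_component(det)
        masks.append(mask)
    return masks
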