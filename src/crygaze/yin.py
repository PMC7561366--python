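"""Frame-level fundamental-frequency estimation (YIN).

The estimator follows the classic autocorrelation-family recipe: squared
difference function over a fixed integration window, cumulative-mean
normalization, absolute-threshold dip picking restricted to the configured
lag band, and parabolic refinement of the selected lag. The value of the
normalized difference function at the chosen lag is reported as the frame's
aperiodicity; frames whose aperiodicity exceeds the configured tolerance
carry no F0 estimate.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .types import PitchFrame, YinConfig

__all__ = [
    "frame_signal",
    "frame_times",
    "difference_function",
    "cumulative_mean_normalized",
    "estimate_pitch_frame",
    "estimate_pitch_frames",
]


def frame_signal(samples: np.ndarray, sample_rate_hz: int, cfg: YinConfig) -> np.ndarray:
    """Slice ``samples`` into overlapping frames.

    Frames have exactly ``round(frame_len_ms * rate / 1000)`` samples and
    successive frame starts are ``round(hop_ms * rate / 1000)`` samples
    apart; a trailing partial frame is discarded. Returns an array of shape
    ``(n_frames, frame_len)`` (possibly zero rows).
    """
    samples = np.asarray(samples, dtype=np.float64)
    w = cfg.frame_len(sample_rate_hz)
    h = cfg.hop(sample_rate_hz)
    n = len(samples)
    if n < w:
        return np.empty((0, w))
    n_frames = (n - w) // h + 1
    idx = np.arange(w)[None, :] + h * np.arange(n_frames)[:, None]
    return samples[idx]


def frame_times(n_samples: int, sample_rate_hz: int, cfg: YinConfig,
                offset_s: float = 0.0) -> np.ndarray:
    """Frame-center times (seconds) matching :func:`frame_signal`."""
    w = cfg.frame_len(sample_rate_hz)
    h = cfg.hop(sample_rate_hz)
    if n_samples < w:
        return np.empty(0)
    n_frames = (n_samples - w) // h + 1
    starts = h * np.arange(n_frames)
    return offset_s + (starts + w / 2) / sample_rate_hz


def difference_function(frames: np.ndarray, tau_max: int) -> np.ndarray:
    """Squared difference function d(tau) for tau = 0..tau_max.

    Uses a fixed integration window of ``W - tau_max`` samples so every lag
    is summed over the same number of terms:

        d(tau) = sum_{j<N} (x[j] - x[j+tau])^2,  N = W - tau_max.

    Computed via FFT cross-correlation; shape ``(n_frames, tau_max + 1)``.
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    n_frames, w = frames.shape
    if tau_max >= w:
        raise ValueError("tau_max must be smaller than the frame length")
    n = w - tau_max
    # c[tau] = sum_{j<N} x[j] x[j+tau] for tau = 0..tau_max
    nfft = 1 << int(np.ceil(np.log2(2 * w)))
    spec = np.fft.rfft(frames, nfft)
    spec_head = np.fft.rfft(frames[:, :n], nfft)
    c = np.fft.irfft(spec * np.conj(spec_head), nfft)[:, : tau_max + 1]
    sq = frames**2
    csum = np.concatenate(
        [np.zeros((n_frames, 1)), np.cumsum(sq, axis=1)], axis=1
    )
    e0 = csum[:, n] - csum[:, 0]  # energy of x[0:N]
    taus = np.arange(tau_max + 1)
    e_tau = csum[:, taus + n] - csum[:, taus]  # energy of x[tau:tau+N]
    d = e0[:, None] + e_tau - 2 * c
    return np.maximum(d, 0.0)


def cumulative_mean_normalized(d: np.ndarray) -> np.ndarray:
    """Cumulative-mean-normalized difference d'(tau); d'(0) = 1.

    d'(tau) = d(tau) * tau / sum_{j<=tau} d(j). Lags with zero cumulative
    sum (a constant frame) normalize to 1, i.e. maximally aperiodic.
    """
    d = np.atleast_2d(d)
    cum = np.cumsum(d[:, 1:], axis=1)
    out = np.ones_like(d)
    taus = np.arange(1, d.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        out[:, 1:] = np.where(cum > 0, d[:, 1:] * taus / cum, 1.0)
    return out


def _parabolic_refine(cmnd_row: np.ndarray, tau: int) -> tuple[float, float]:
    """Refine an integer lag by fitting a parabola through its neighbours.

    Returns (refined_lag, refined_min_value); falls back to the integer lag
    at the array boundaries or for a degenerate (non-convex) fit.
    """
    if tau <= 0 or tau >= len(cmnd_row) - 1:
        return float(tau), float(cmnd_row[tau])
    a, b, c = cmnd_row[tau - 1], cmnd_row[tau], cmnd_row[tau + 1]
    denom = a - 2 * b + c
    if denom <= 0:
        return float(tau), float(b)
    shift = 0.5 * (a - c) / denom
    shift = float(np.clip(shift, -0.5, 0.5))
    value = b - 0.25 * (a - c) * shift
    return tau + shift, float(value)


def _pick_lag(cmnd_row: np.ndarray, tau_min: int, tau_max: int,
              threshold: float) -> int:
    """First lag in [tau_min, tau_max] dipping below ``threshold``.

    After the first sub-threshold lag, the pick walks downhill to the local
    minimum of that dip. Without any sub-threshold dip the global minimum in
    the band is returned.
    """
    band = cmnd_row[tau_min : tau_max + 1]
    below = np.nonzero(band < threshold)[0]
    if below.size:
        tau = tau_min + int(below[0])
        while tau + 1 <= tau_max and cmnd_row[tau + 1] < cmnd_row[tau]:
            tau += 1
        return tau
    return tau_min + int(np.argmin(band))


def estimate_pitch_frames(frames: np.ndarray, sample_rate_hz: int,
                          cfg: YinConfig,
                          times_s: Optional[np.ndarray] = None) -> list[PitchFrame]:
    """Estimate F0 and aperiodicity for a batch of frames."""
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    n_frames = frames.shape[0]
    if times_s is None:
        times_s = np.zeros(n_frames)
    tau_min, tau_max = cfg.lag_range(sample_rate_hz)
    d = difference_function(frames, tau_max)
    cmnd = cumulative_mean_normalized(d)
    out: list[PitchFrame] = []
    ptp = frames.max(axis=1) - frames.min(axis=1)
    for i in range(n_frames):
        row = cmnd[i]
        if ptp[i] == 0:  # constant frame: no periodicity evidence
            out.append(PitchFrame(float(times_s[i]), None, 1.0))
            continue
        tau = _pick_lag(row, tau_min, tau_max, cfg.aperiodicity_threshold)
        lag, ap = _parabolic_refine(row, tau)
        ap = max(ap, 0.0)
        f0: Optional[float] = sample_rate_hz / lag
        # clip interpolation slip at the band edges
        f0 = min(max(f0, cfg.f0_min_hz), cfg.f0_max_hz)
        if ap > cfg.aperiodicity_threshold:
            f0 = None
        out.append(PitchFrame(float(times_s[i]), f0, float(ap)))
    return out


def estimate_pitch_frame(frame: np.ndarray, sample_rate_hz: int,
                         cfg: YinConfig, time_s: float = 0.0) -> PitchFrame:
    """Single-frame convenience wrapper around :func:`estimate_pitch_frames`."""
    return estimate_pitch_frames(
        np.asarray(frame)[None, :], sample_rate_hz, cfg, np.array([time_s])
    )[0]
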