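"""Three-way segmentation of cry recordings.

Splits a recording into expiratory, inspiratory and residual regions by a
frame-level classifier: short-time energy separates sound from silence,
harmonicity (the normalized-difference aperiodicity used by the pitch
stage) identifies voiced expiratory cry, and the mid-band spectral
concentration typical of breathy ingressive sounds separates inspiratory
noise from other, broadband residual sound. Labels are median-smoothed and
runs shorter than a minimum duration are dropped, so the output is a sorted
list of non-overlapping segments; silence belongs to no segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import medfilt

from .types import (
    EXPIRATORY,
    INSPIRATORY,
    RESIDUAL,
    AudioRecording,
    CrySegment,
    YinConfig,
)
from .yin import cumulative_mean_normalized, difference_function, frame_signal

__all__ = ["SegmentationConfig", "segment_recording"]

_SILENCE, _EXP, _INSP, _RES = 0, 1, 2, 3
_CODE_TO_LABEL = {_EXP: EXPIRATORY, _INSP: INSPIRATORY, _RES: RESIDUAL}


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunables of the stand-in segmenter.

    silence_rel_threshold: frame RMS below this fraction of the recording's
        95th-percentile RMS counts as silence (plus an absolute floor).
    harmonic_ap_threshold: frames at or below this aperiodicity are voiced.
    insp_band_hz: band whose energy concentration marks inspiratory noise.
    insp_band_min_fraction: in-band energy fraction above which an unvoiced
        frame is called inspiratory rather than residual.
    median_width_frames: odd width of the label median filter.
    min_segment_dur_ms: runs shorter than this are discarded.
    """

    silence_rel_threshold: float = 0.05
    silence_abs_floor: float = 1e-4
    harmonic_ap_threshold: float = 0.3
    insp_band_hz: tuple[float, float] = (2000.0, 6000.0)
    insp_band_min_fraction: float = 0.55
    median_width_frames: int = 5
    min_segment_dur_ms: float = 100.0


def _frame_features(frames: np.ndarray, sample_rate_hz: int, cfg: YinConfig):
    """Per-frame (rms, aperiodicity, inspiratory-band energy fraction)."""
    rms = np.sqrt(np.mean(frames**2, axis=1))
    _, tau_max = cfg.lag_range(sample_rate_hz)
    d = difference_function(frames, tau_max)
    cmnd = cumulative_mean_normalized(d)
    tau_min, _ = cfg.lag_range(sample_rate_hz)
    ap = cmnd[:, tau_min : tau_max + 1].min(axis=1)
    ap[~np.any(d[:, 1:] > 0, axis=1)] = 1.0
    return rms, ap


def _band_fraction(frames: np.ndarray, sample_rate_hz: int,
                   band: tuple[float, float]) -> np.ndarray:
    spec = np.abs(np.fft.rfft(frames, axis=1)) ** 2
    freqs = np.fft.rfftfreq(frames.shape[1], 1.0 / sample_rate_hz)
    total = spec.sum(axis=1)
    in_band = spec[:, (freqs >= band[0]) & (freqs <= band[1])].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, in_band / total, 0.0)
    return frac


def segment_recording(rec: AudioRecording, cfg: YinConfig | None = None,
                      seg_cfg: SegmentationConfig | None = None) -> list[CrySegment]:
    """Partition the sounding parts of ``rec`` into labeled segments."""
    cfg = cfg or YinConfig()
    seg_cfg = seg_cfg or SegmentationConfig()
    frames = frame_signal(rec.samples, rec.sample_rate_hz, cfg)
    if frames.shape[0] == 0:
        return []
    rms, ap = _frame_features(frames, rec.sample_rate_hz, cfg)
    band_frac = _band_fraction(frames, rec.sample_rate_hz, seg_cfg.insp_band_hz)

    loud = np.percentile(rms, 95)
    silence_thr = max(seg_cfg.silence_abs_floor,
                      seg_cfg.silence_rel_threshold * loud)
    codes = np.full(len(rms), _RES, dtype=int)
    codes[band_frac > seg_cfg.insp_band_min_fraction] = _INSP
    codes[ap <= seg_cfg.harmonic_ap_threshold] = _EXP
    codes[rms < silence_thr] = _SILENCE

    width = seg_cfg.median_width_frames | 1  # force odd
    if len(codes) >= width:
        codes = medfilt(codes, kernel_size=width)

    hop = cfg.hop(rec.sample_rate_hz)
    w = cfg.frame_len(rec.sample_rate_hz)
    segments: list[CrySegment] = []
    i = 0
    while i < len(codes):
        j = i
        while j < len(codes) and codes[j] == codes[i]:
            j += 1
        if codes[i] != _SILENCE:
            start_s = i * hop / rec.sample_rate_hz
            # extend to the full frame only at the end of the stream so that
            # adjacent runs never overlap
            if j < len(codes):
                end_s = j * hop / rec.sample_rate_hz
            else:
                end_s = ((j - 1) * hop + w) / rec.sample_rate_hz
            if (end_s - start_s) * 1000.0 >= seg_cfg.min_segment_dur_ms:
                segments.append(
                    CrySegment(start_s, end_s, _CODE_TO_LABEL[int(codes[i])])
                )
        i = j
    # median smoothing cannot produce overlap, but clamp against rounding
    for a, b in zip(segments, segments[1:]):
        assert b.start_s >= a.end_s - 1e-9
    return segments
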