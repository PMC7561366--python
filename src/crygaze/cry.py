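"""Participant-level cry features: F0 and F0var.

Pipeline per recording: segment into expiratory/inspiratory/residual
regions, pitch-track each expiratory phase frame by frame, discard frames
whose aperiodicity exceeds 0.3, drop phases shorter than 500 ms or with
more than 70% inharmonic frames, keep the first (up to five) surviving
phases in temporal order, and average the per-phase F0 means (-> F0) and
per-phase F0 standard deviations (-> F0var). Recordings with fewer than
three scorable phases are unusable.
"""

from __future__ import annotations

import math
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .segmentation import SegmentationConfig, segment_recording
from .types import (
    EXPIRATORY,
    AudioRecording,
    CryFeatures,
    CrySegment,
    PhasePitchTrack,
    UnusableRecordingError,
    YinConfig,
)
from .yin import estimate_pitch_frames, frame_signal, frame_times

__all__ = [
    "track_phase",
    "select_phases",
    "compute_features",
    "extract_cry_features",
    "features_to_frame",
    "diagnostics_to_frame",
]


def track_phase(segment: CrySegment, rec: AudioRecording,
                cfg: YinConfig | None = None) -> PhasePitchTrack:
    """Pitch-track one expiratory phase and compute its retained statistics.

    Frames with aperiodicity above the configured tolerance are counted as
    inharmonic and excluded from the phase mean/SD; with no surviving frame
    the statistics are absent and the phase is unusable.
    """
    cfg = cfg or YinConfig()
    if segment.label != EXPIRATORY:
        raise ValueError("track_phase expects an expiratory segment")
    sr = rec.sample_rate_hz
    lo = int(round(segment.start_s * sr))
    hi = int(round(segment.end_s * sr))
    chunk = rec.samples[lo:hi]
    frames = frame_signal(chunk, sr, cfg)
    times = frame_times(len(chunk), sr, cfg, offset_s=segment.start_s)
    pitch_frames = estimate_pitch_frames(frames, sr, cfg, times)
    n = len(pitch_frames)
    retained = [f.f0_hz for f in pitch_frames if f.f0_hz is not None]
    inharmonic_fraction = (n - len(retained)) / n if n else 1.0
    if retained:
        mean = float(np.mean(retained))
        sd = float(np.std(retained, ddof=1)) if len(retained) > 1 else 0.0
    else:
        mean = sd = None
    return PhasePitchTrack(
        segment=segment,
        frames=pitch_frames,
        inharmonic_fraction=inharmonic_fraction,
        phase_f0_mean_hz=mean,
        phase_f0_sd_hz=sd,
    )


def select_phases(tracks: Sequence[PhasePitchTrack],
                  cfg: YinConfig | None = None) -> list[PhasePitchTrack]:
    """Apply the duration and harmonicity filters, keep the first survivors.

    Phases must be strictly longer than ``min_phase_dur_ms`` and have an
    inharmonic-frame fraction of at most ``max_inharmonic_fraction`` (and a
    usable mean); of the survivors, the temporally first ``max_phases`` are
    kept. Fewer than ``min_phases`` survivors raises
    :class:`UnusableRecordingError` carrying the count.
    """
    cfg = cfg or YinConfig()
    ordered = sorted(tracks, key=lambda t: t.segment.start_s)
    survivors = [
        t
        for t in ordered
        if t.segment.duration_s * 1000.0 > cfg.min_phase_dur_ms
        and t.inharmonic_fraction <= cfg.max_inharmonic_fraction
        and t.usable
    ]
    selected = survivors[: cfg.max_phases]
    if len(selected) < cfg.min_phases:
        raise UnusableRecordingError(len(selected), cfg.min_phases)
    return selected


def compute_features(selected: Sequence[PhasePitchTrack],
                     cfg: YinConfig | None = None) -> CryFeatures:
    """Aggregate selected phases: F0 = mean of means, F0var = mean of SDs."""
    cfg = cfg or YinConfig()
    if not (cfg.min_phases <= len(selected) <= cfg.max_phases):
        raise ValueError(
            f"compute_features needs {cfg.min_phases}..{cfg.max_phases} phases,"
            f" got {len(selected)}"
        )
    means = [t.phase_f0_mean_hz for t in selected]
    sds = [t.phase_f0_sd_hz for t in selected]
    if any(m is None for m in means):
        raise ValueError("all selected phases must carry statistics")
    return CryFeatures(
        f0_hz=float(np.mean(means)),
        f0var_hz=float(np.mean(sds)),
        n_phases_used=len(selected),
        per_phase_means=[float(m) for m in means],
        per_phase_sds=[float(s) for s in sds],
        usable=True,
    )


def extract_cry_features(rec: AudioRecording, cfg: YinConfig | None = None,
                         seg_cfg: SegmentationConfig | None = None,
                         ) -> tuple[CryFeatures, list[PhasePitchTrack]]:
    """Full per-recording pipeline; returns features plus all phase tracks.

    On an unusable recording the returned features carry ``usable=False``
    and NaN feature values (no exception), so batch runs keep going.
    """
    cfg = cfg or YinConfig()
    segments = segment_recording(rec, cfg, seg_cfg)
    tracks = [
        track_phase(s, rec, cfg) for s in segments if s.label == EXPIRATORY
    ]
    try:
        selected = select_phases(tracks, cfg)
    except UnusableRecordingError as err:
        return (
            CryFeatures(
                f0_hz=math.nan,
                f0var_hz=math.nan,
                n_phases_used=err.n_phases,
                usable=False,
            ),
            tracks,
        )
    return compute_features(selected, cfg), tracks


def features_to_frame(rows: Iterable[tuple[str, CryFeatures, bool]]) -> pd.DataFrame:
    """Per-recording feature table: (recording_id, features, bout flag) rows."""
    return pd.DataFrame(
        [
            {
                "recording_id": rid,
                "f0_hz": feats.f0_hz,
                "f0var_hz": feats.f0var_hz,
                "n_phases_used": feats.n_phases_used,
                "usable": feats.usable,
                "bout_start_captured": bout,
            }
            for rid, feats, bout in rows
        ]
    )


def diagnostics_to_frame(rows: Iterable[tuple[str, Sequence[PhasePitchTrack]]]
                         ) -> pd.DataFrame:
    """Per-phase diagnostics table for inspection of the filtering rules."""
    records = []
    for rid, tracks in rows:
        for t in tracks:
            records.append(
                {
                    "recording_id": rid,
                    "start_s": t.segment.start_s,
                    "end_s": t.segment.end_s,
                    "n_frames": t.n_frames,
                    "n_retained": t.n_retained,
                    "inharmonic_fraction": t.inharmonic_fraction,
                    "phase_mean": t.phase_f0_mean_hz,
                    "phase_sd": t.phase_f0_sd_hz,
                }
            )
    return pd.DataFrame(records)


def process_wav_files(paths: Sequence[str | os.PathLike],
                      cfg: YinConfig | None = None,
                      bout_start_captured: bool = False,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Batch entry point used by the command-line tool."""
    from .audio_io import load_recording

    feats_rows, diag_rows = [], []
    for p in paths:
        rec = load_recording(p, bout_start_captured=bout_start_captured)
        rid = os.path.splitext(os.path.basename(os.fspath(p)))[0]
        feats, tracks = extract_cry_features(rec, cfg)
        feats_rows.append((rid, feats, rec.bout_start_captured))
        diag_rows.append((rid, tracks))
    return features_to_frame(feats_rows), diagnostics_to_frame(diag_rows)
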