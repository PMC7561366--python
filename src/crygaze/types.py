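"""Domain types shared across the cry-acoustics and gaze-attention stages.

All dataclasses are plain containers; invariants that matter numerically
(e.g. F0 search band inside Nyquist) are enforced in ``__post_init__`` or by
the producing function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

EXPIRATORY = "expiratory"
INSPIRATORY = "inspiratory"
RESIDUAL = "residual"
SEGMENT_LABELS = (EXPIRATORY, INSPIRATORY, RESIDUAL)

DISENGAGEMENT_CONDITIONS = ("happy", "fearful", "nonface")


@dataclass
class AudioRecording:
    """A mono, [-1, 1]-normalized cry recording."""

    samples: np.ndarray
    sample_rate_hz: int
    n_channels: int = 1
    source_path: str = ""
    bout_start_captured: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioRecording holds a single analysis channel")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz


@dataclass(frozen=True)
class CrySegment:
    """One labeled region of a recording (times in seconds)."""

    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("segment must have positive duration")
        if self.label not in SEGMENT_LABELS:
            raise ValueError(f"unknown segment label {self.label!r}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class YinConfig:
    """Framing, pitch-search and phase-filtering parameters.

    ``aperiodicity_threshold`` plays the double role it has in YIN: the
    absolute threshold for picking the first dip of the cumulative-mean-
    normalized difference function, and the tolerance above which a frame's
    F0 estimate is discarded as inharmonic.
    """

    frame_len_ms: float = 25.0
    hop_ms: float = 12.5
    f0_min_hz: float = 200.0
    f0_max_hz: float = 700.0
    aperiodicity_threshold: float = 0.3
    min_phase_dur_ms: float = 500.0
    max_inharmonic_fraction: float = 0.7
    max_phases: int = 5
    min_phases: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.f0_min_hz < self.f0_max_hz):
            raise ValueError("need 0 < f0_min_hz < f0_max_hz")
        if self.hop_ms > self.frame_len_ms:
            raise ValueError("hop_ms must not exceed frame_len_ms")
        if not (0 < self.aperiodicity_threshold < 1):
            raise ValueError("aperiodicity_threshold must lie in (0, 1)")
        if not (0 < self.max_inharmonic_fraction < 1):
            raise ValueError("max_inharmonic_fraction must lie in (0, 1)")

    def frame_len(self, sample_rate_hz: int) -> int:
        return int(round(self.frame_len_ms * sample_rate_hz / 1000.0))

    def hop(self, sample_rate_hz: int) -> int:
        return int(round(self.hop_ms * sample_rate_hz / 1000.0))

    def lag_range(self, sample_rate_hz: int) -> tuple[int, int]:
        """Integer lag bounds [tau_min, tau_max] for the F0 search band."""
        if self.f0_max_hz >= sample_rate_hz / 2:
            raise ValueError("f0_max_hz must be below Nyquist")
        tau_min = max(2, int(np.floor(sample_rate_hz / self.f0_max_hz)))
        tau_max = int(np.ceil(sample_rate_hz / self.f0_min_hz))
        return tau_min, tau_max


@dataclass(frozen=True)
class PitchFrame:
    """Per-frame F0 estimate; ``f0_hz`` is None when the frame is rejected."""

    time_s: float
    f0_hz: Optional[float]
    aperiodicity: float


@dataclass
class PhasePitchTrack:
    """Pitch track of one expiratory phase with its retention statistics."""

    segment: CrySegment
    frames: list[PitchFrame]
    inharmonic_fraction: float
    phase_f0_mean_hz: Optional[float]
    phase_f0_sd_hz: Optional[float]

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_retained(self) -> int:
        return sum(1 for f in self.frames if f.f0_hz is not None)

    @property
    def usable(self) -> bool:
        return self.phase_f0_mean_hz is not None


@dataclass
class CryFeatures:
    """Participant-level acoustic features: F0 and F0var.

    F0 is the mean of the per-phase frame-level F0 means; F0var is the mean
    of the per-phase frame-level F0 standard deviations, over the first (up
    to five) expiratory phases surviving the duration and harmonicity
    filters. A recording is usable only with at least three such phases.
    """

    f0_hz: Optional[float]
    f0var_hz: Optional[float]
    n_phases_used: int
    per_phase_means: list[float] = field(default_factory=list)
    per_phase_sds: list[float] = field(default_factory=list)
    usable: bool = False


class UnusableRecordingError(ValueError):
    """Raised when fewer than ``min_phases`` scorable expiratory phases exist."""

    def __init__(self, n_phases: int, min_phases: int):
        self.n_phases = n_phases
        self.min_phases = min_phases
        super().__init__(
            f"only {n_phases} scorable expiratory phases; {min_phases} required"
        )


# ---------------------------------------------------------------------------
# Gaze types


@dataclass(frozen=True)
class AOI:
    """Screen rectangle in degrees of visual angle (closed bounds)."""

    center_x: float
    center_y: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("AOI width and height must be positive")

    def contains(self, x: float, y: float) -> bool:
        return (
            abs(x - self.center_x) <= self.width / 2
            and abs(y - self.center_y) <= self.height / 2
        )

    def contains_array(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (np.abs(x - self.center_x) <= self.width / 2) & (
            np.abs(y - self.center_y) <= self.height / 2
        )


@dataclass
class TrialRecord:
    """One eye-tracking trial: raw samples plus stimulus-event metadata.

    ``samples`` is a structured array-like of columns (time_ms, x, y, valid),
    sorted by time, with time 0 at trial start.
    """

    trial_id: str
    task: str  # "orienting" | "disengagement"
    condition: str  # "target" | "happy" | "fearful" | "nonface"
    central_aoi: AOI
    lateral_aoi: AOI
    lateral_onset_ms: float
    time_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    x: np.ndarray = field(default_factory=lambda: np.empty(0))
    y: np.ndarray = field(default_factory=lambda: np.empty(0))
    valid: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    def __post_init__(self) -> None:
        if self.task not in ("orienting", "disengagement"):
            raise ValueError(f"unknown task {self.task!r}")
        ok = {"orienting": ("target",), "disengagement": DISENGAGEMENT_CONDITIONS}
        if self.condition not in ok[self.task]:
            raise ValueError(
                f"condition {self.condition!r} invalid for task {self.task!r}"
            )


@dataclass(frozen=True)
class ScoringConfig:
    """Trial-validity and dwell-normalization parameters.

    The dwell window runs from ``window_start_ms`` (shortest acceptable
    saccadic reaction time, mapping to index 0) to ``window_end_ms`` (no
    shift, mapping to 1); ``norm_range_ms`` must equal their difference.
    """

    fixation_min_fraction: float = 0.7
    max_gap_ms: float = 200.0
    window_start_ms: float = 150.0
    window_end_ms: float = 1000.0
    norm_range_ms: float = 850.0
    min_orienting_trials: int = 4
    min_trials_per_condition: int = 3
    screen_half_width_deg: float = 13.5
    screen_half_height_deg: float = 10.5

    def __post_init__(self) -> None:
        if abs((self.window_end_ms - self.window_start_ms) - self.norm_range_ms) > 1e-9:
            raise ValueError("norm_range_ms must equal window_end_ms - window_start_ms")
        for name in ("fixation_min_fraction", "max_gap_ms", "window_start_ms",
                     "window_end_ms", "norm_range_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


VALID_SHIFT = "valid_shift"
VALID_NO_SHIFT = "valid_no_shift"
INVALID = "invalid"

EXCLUSION_REASONS = (
    "insufficient_fixation",
    "data_gap",
    "shift_in_gap",
    "off_screen",
    "too_early",
    "too_late",
)


@dataclass(frozen=True)
class TrialScore:
    """Outcome of scoring one trial."""

    trial_id: str
    task: str
    condition: str
    status: str  # valid_shift | valid_no_shift | invalid
    reason: Optional[str] = None
    saccade_time_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status == VALID_SHIFT and self.saccade_time_ms is None:
            raise ValueError("valid_shift requires saccade_time_ms")
        if self.status == INVALID and self.reason not in EXCLUSION_REASONS:
            raise ValueError(f"invalid score needs a known reason, got {self.reason!r}")


@dataclass
class ParticipantAttention:
    """Participant-level orienting latency and dwell-time index."""

    participant_id: str
    orienting_latency_ms: Optional[float]
    n_orienting_trials: int
    dwell_index_by_condition: dict[str, Optional[float]]
    dwell_index: Optional[float]
    included_orienting: bool
    included_dwell: bool


# ---------------------------------------------------------------------------
# Cohort statistics types


@dataclass(frozen=True)
class Descriptives:
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_two_tailed: float
    cohen_d: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_two_tailed: float
    n: int


def segments_partition_ok(segments: Sequence[CrySegment]) -> bool:
    """True when segments are sorted and non-overlapping."""
    for a, b in zip(segments, segments[1:]):
        if b.start_s < a.end_s - 1e-9:
            return False
    return True
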