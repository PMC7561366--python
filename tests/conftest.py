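import numpy as np
import pytest

from crygaze.types import AOI, ScoringConfig, TrialRecord, YinConfig

SR = 48000


@pytest.fixture(scope="session")
def yin_cfg() -> YinConfig:
    return YinConfig()


@pytest.fixture(scope="session")
def scoring_cfg() -> ScoringConfig:
    return ScoringConfig()


def sine_frame(freq_hz: float, sr: int = SR, dur_ms: float = 25.0,
               phase: float = 0.0) -> np.ndarray:
    t = np.arange(int(round(dur_ms * sr / 1000.0))) / sr
    return np.sin(2 * np.pi * freq_hz * t + phase)


def harmonic_frame(f0_hz: float, n_harmonics: int = 5, sr: int = SR,
                   dur_ms: float = 25.0) -> np.ndarray:
    t = np.arange(int(round(dur_ms * sr / 1000.0))) / sr
    return sum(
        (0.8 ** (h - 1)) * np.sin(2 * np.pi * h * f0_hz * t)
        for h in range(1, n_harmonics + 1)
    )


CENTRAL = AOI(0.0, 0.0, 5.0, 5.0)
LATERAL = AOI(15.0, 0.0, 10.9, 9.5)
ONSET_MS = 1000.0


def build_trial(
    shift_at_ms=None,
    task="disengagement",
    condition="happy",
    trial_id="t0",
    onset_ms=ONSET_MS,
    tail_ms=1200.0,
    dt_ms=1000.0 / 300.0,
    gap_ms=None,  # (start, duration) of an invalid-sample run
    fixate_fraction=1.0,  # fraction of pre-shift samples inside central AOI
    off_screen_before_shift=False,
    extra_times=(),
) -> TrialRecord:
    """Hand-built trial: central fixation, optional step to the lateral AOI.

    ``shift_at_ms`` is relative to lateral onset; ``extra_times`` inserts
    additional absolute timestamps (e.g. to place a sample exactly at the
    window edge).
    """
    times = np.arange(0.0, onset_ms + tail_ms, dt_ms)
    if extra_times:
        times = np.unique(np.concatenate([times, np.asarray(extra_times, float)]))
    n = len(times)
    x = np.zeros(n)
    y = np.zeros(n)
    if fixate_fraction < 1.0:
        k = int(round((1.0 - fixate_fraction) * n))
        stray = np.linspace(0, n - 1, k).astype(int)  # spread strays evenly
        x[stray] = 9.0  # inside screen, outside both AOIs
    if shift_at_ms is not None:
        shifted = times >= onset_ms + shift_at_ms
        x[shifted] = LATERAL.center_x
        y[shifted] = LATERAL.center_y
        if off_screen_before_shift:
            # first two post-saccade samples land beyond the screen edge
            # (and outside the lateral AOI) before the gaze reaches the target
            x[np.nonzero(shifted)[0][:2]] = 25.0
    valid = np.ones(n, dtype=bool)
    if gap_ms is not None:
        g0, gdur = gap_ms
        valid[(times >= g0) & (times < g0 + gdur)] = False
    return TrialRecord(
        trial_id=trial_id,
        task=task,
        condition=condition,
        central_aoi=CENTRAL,
        lateral_aoi=LATERAL,
        lateral_onset_ms=onset_ms,
        time_ms=times,
        x=x,
        y=y,
        valid=valid,
    )
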