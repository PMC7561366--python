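"""WAV reading/writing for cry recordings.

Recordings are expected as 48-kHz PCM WAV (mono or stereo); any bit depth
readable by ``scipy.io.wavfile`` is accepted and normalized to [-1, 1].
Stereo is mixed down to mono by the channel mean before analysis.
"""

from __future__ import annotations

import os

import numpy as np
from scipy.io import wavfile

from .types import AudioRecording

__all__ = ["load_recording", "write_wav"]

_PCM_FULL_SCALE = {
    np.dtype(np.int16): 2**15,
    np.dtype(np.int32): 2**31,
    np.dtype(np.uint8): 2**7,
}


class WavFormatError(ValueError):
    pass


def load_recording(path: str | os.PathLike,
                   bout_start_captured: bool = False) -> AudioRecording:
    """Read a WAV file into a mono, [-1, 1]-normalized :class:`AudioRecording`.

    Raises :class:`WavFormatError` naming the path for unreadable files and
    ``ValueError`` for zero-length audio.
    """
    path = os.fspath(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise WavFormatError(f"not a readable WAV file: {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"zero-length audio: {path}")
    data = np.atleast_1d(data)
    n_channels = 1 if data.ndim == 1 else data.shape[1]
    dtype = data.dtype
    samples = data.astype(np.float64)
    if dtype in _PCM_FULL_SCALE:
        if dtype == np.dtype(np.uint8):  # 8-bit WAV is unsigned
            samples = samples - 128.0
        samples = samples / _PCM_FULL_SCALE[dtype]
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioRecording(
        samples=samples,
        sample_rate_hz=int(rate),
        n_channels=n_channels,
        source_path=path,
        bout_start_captured=bout_start_captured,
    )


def write_wav(path: str | os.PathLike, samples: np.ndarray,
              sample_rate_hz: int) -> None:
    """Write float samples in [-1, 1] as 16-bit PCM WAV."""
    samples = np.asarray(samples, dtype=np.float64)
    peak = np.max(np.abs(samples)) if samples.size else 0.0
    if peak > 1.0:
        samples = samples / peak
    pcm = np.round(samples * (2**15 - 1)).astype(np.int16)
    wavfile.write(os.fspath(path), int(sample_rate_hz), pcm)
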