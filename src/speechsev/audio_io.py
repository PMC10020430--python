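"""WAV reading/writing and the canonical mono float signal type.

All downstream stages consume :class:`AudioSignal` at the package-wide
canonical rate of 16 kHz mono with float samples nominally in [-1, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import FormatError, InputError, ParameterError

#: Canonical internal sample rate (Hz); speech band content <= 8 kHz.
CANONICAL_RATE = 16_000

# Full-scale divisors for integer PCM dialects.
_PCM_SCALE = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
    np.dtype(np.uint8): 128.0,
}


@dataclass(frozen=True)
class AudioSignal:
    """A mono sampled waveform.

    Attributes
    ----------
    samples:
        1-D float64 array of amplitudes, nominally in [-1, 1].
    sample_rate:
        Sampling rate in Hz, > 0.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise InputError("AudioSignal samples must be 1-D (mono)")
        if samples.size == 0:
            raise InputError("AudioSignal samples must be non-empty")
        if self.sample_rate <= 0:
            raise ParameterError(f"sample_rate must be > 0, got {self.sample_rate}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.sample_rate

    def __len__(self) -> int:
        return self.samples.size


def read_wav(path: str | Path) -> AudioSignal:
    """Read a WAV file as a mono :class:`AudioSignal` at its native rate.

    Multi-channel audio is averaged to mono; integer PCM is rescaled to
    [-1, 1] by the full-scale value of its dtype.

    Raises
    ------
    InputError
        If the file does not exist.
    FormatError
        If the file is not a readable WAV file.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"audio file not found: {path}")
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise FormatError(f"not a readable WAV file: {path} ({exc})") from exc
    if data.ndim == 2:
        data = data.astype(np.float64).mean(axis=1)
    if data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    else:
        samples = data.astype(np.float64)
    return AudioSignal(samples=samples, sample_rate=int(rate))


def write_wav(path: str | Path, sig: AudioSignal) -> None:
    """Write ``sig`` as a 32-bit IEEE-float WAV file."""
    wavfile.write(Path(path), sig.sample_rate, sig.samples.astype(np.float32))


def resample(sig: AudioSignal, target_rate: int) -> AudioSignal:
    """Band-limited resampling to ``target_rate`` Hz.

    Identity when the rate already matches. Uses polyphase filtering,
    preserving duration within one sample period.
    """
    if target_rate <= 0:
        raise ParameterError(f"target_rate must be > 0, got {target_rate}")
    if target_rate == sig.sample_rate:
        return sig
    g = math.gcd(int(target_rate), int(sig.sample_rate))
    up, down = target_rate // g, sig.sample_rate // g
    samples = resample_poly(sig.samples, up, down)
    return AudioSignal(samples=samples, sample_rate=int(target_rate))


def to_canonical(sig: AudioSignal) -> AudioSignal:
    """Resample to the canonical internal rate (16 kHz)."""
    return resample(sig, CANONICAL_RATE)
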