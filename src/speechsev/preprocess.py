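"""Amplitude normalization and spectral-subtraction denoising.

The denoiser splits the recording into speech and voiceless frames with a
short-time-RMS voice activity detector, averages the STFT magnitude of the
voiceless frames into a noise profile, and subtracts that profile per
frequency bin from every frame (magnitude subtraction with a multiplicative
floor), reconstructing with the original phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _stft
from .audio_io import AudioSignal
from .errors import ConsistencyError, InputError, ParameterError

logger = logging.getLogger(__name__)

DEFAULT_TARGET_PEAK = 0.99
DEFAULT_FLOOR_FRAC = 0.02
_FALLBACK_QUIET_FRAC = 0.1  # quietest 10% marked voiceless if VAD finds none


@dataclass(frozen=True)
class VoicingMask:
    """Per-frame speech/voiceless flags on the shared STFT grid."""

    frame_length: int
    hop_length: int
    is_speech: np.ndarray  # bool per frame

    def __post_init__(self) -> None:
        flags = np.asarray(self.is_speech, dtype=bool)
        if flags.size == 0:
            raise InputError("VoicingMask must contain at least one frame")
        object.__setattr__(self, "is_speech", flags)

    @property
    def n_frames(self) -> int:
        return self.is_speech.size


@dataclass(frozen=True)
class NoiseProfile:
    """Mean STFT magnitude of the voiceless frames, per frequency bin."""

    mean_magnitude: np.ndarray
    n_frames_used: int

    def __post_init__(self) -> None:
        mag = np.asarray(self.mean_magnitude, dtype=np.float64)
        if np.any(mag < 0):
            raise ParameterError("noise profile magnitudes must be >= 0")
        if self.n_frames_used < 1:
            raise ParameterError("noise profile needs >= 1 voiceless frame")
        object.__setattr__(self, "mean_magnitude", mag)


def normalize_amplitude(
    sig: AudioSignal, target_peak: float = DEFAULT_TARGET_PEAK
) -> AudioSignal:
    """Scale so the maximum absolute sample equals ``target_peak``.

    An all-zero signal is returned unchanged with a logged warning.
    """
    if not 0.0 < target_peak <= 1.0:
        raise ParameterError(f"target_peak must be in (0, 1], got {target_peak}")
    peak = np.max(np.abs(sig.samples))
    if peak == 0.0:
        logger.warning("normalize_amplitude: all-zero signal left unchanged")
        return sig
    return AudioSignal(sig.samples * (target_peak / peak), sig.sample_rate)


def segment_speech_silence(
    sig: AudioSignal,
    frame_length: int | None = None,
    hop_length: int | None = None,
) -> VoicingMask:
    """Mark frames as speech when short-time RMS exceeds an adaptive threshold.

    The threshold is the geometric mean of the 10th and 90th percentiles of
    frame RMS. If every frame passes (near-constant amplitude), the
    quietest 10% of frames are marked voiceless as a fallback, so at least
    one voiceless frame always exists.
    """
    geom = _geometry(sig, frame_length, hop_length)
    if len(sig) < geom.frame_length:
        raise InputError("signal shorter than one analysis frame")
    spectrum = _stft.stft(sig.samples, geom)
    return _mask_from_spectrum(spectrum, geom)


def _mask_from_spectrum(
    spectrum: np.ndarray, geom: _stft.StftGeometry
) -> VoicingMask:
    rms = _stft.frame_rms(spectrum, geom)
    p10, p90 = np.percentile(rms, [10.0, 90.0])
    threshold = np.sqrt(p10 * p90)
    is_speech = rms > threshold
    n_quiet = int(np.ceil(_FALLBACK_QUIET_FRAC * rms.size))
    if p90 > 0 and (not is_speech.any() or (~is_speech).sum() < n_quiet):
        # degenerate RMS distribution (near-constant amplitude): fall back
        # to marking exactly the quietest 10% of frames voiceless
        quiet = np.argsort(rms, kind="stable")[:n_quiet]
        is_speech = np.ones(rms.size, dtype=bool)
        is_speech[quiet] = False
    return VoicingMask(
        frame_length=geom.frame_length, hop_length=geom.hop_length, is_speech=is_speech
    )


def estimate_noise(sig: AudioSignal, mask: VoicingMask) -> NoiseProfile:
    """Per-bin mean STFT magnitude over the voiceless frames of ``mask``."""
    geom = _geometry(sig, mask.frame_length, mask.hop_length)
    spectrum = _stft.stft(sig.samples, geom)
    if spectrum.shape[1] != mask.n_frames:
        raise ConsistencyError(
            f"mask has {mask.n_frames} frames but signal yields "
            f"{spectrum.shape[1]} STFT frames"
        )
    voiceless = ~mask.is_speech
    if not np.any(voiceless):
        raise ConsistencyError("mask contains no voiceless frames")
    profile = np.abs(spectrum[:, voiceless]).mean(axis=1)
    return NoiseProfile(mean_magnitude=profile, n_frames_used=int(voiceless.sum()))


def spectral_subtract(
    sig: AudioSignal,
    noise: NoiseProfile,
    floor_frac: float = DEFAULT_FLOOR_FRAC,
) -> AudioSignal:
    """Subtract the noise profile from every frame's STFT magnitude.

    Per frame and bin the magnitude ``m`` becomes
    ``max(m - noise_bin, floor_frac * m)``; phase is preserved and the
    signal is reconstructed by inverse STFT at the input length.
    """
    if floor_frac < 0:
        raise ParameterError(f"floor_frac must be >= 0, got {floor_frac}")
    geom = _stft.default_geometry(sig.sample_rate)
    spectrum = _stft.stft(sig.samples, geom)
    samples = _subtract_from_spectrum(spectrum, noise, floor_frac, geom, len(sig))
    return AudioSignal(samples=samples, sample_rate=sig.sample_rate)


def _subtract_from_spectrum(
    spectrum: np.ndarray,
    noise: NoiseProfile,
    floor_frac: float,
    geom: _stft.StftGeometry,
    n_samples: int,
) -> np.ndarray:
    if noise.mean_magnitude.size != spectrum.shape[0]:
        raise ConsistencyError(
            f"noise profile has {noise.mean_magnitude.size} bins, "
            f"STFT has {spectrum.shape[0]}"
        )
    mag = np.abs(spectrum)
    cleaned = np.maximum(mag - noise.mean_magnitude[:, None], floor_frac * mag)
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = np.where(mag > 0, cleaned / mag, 0.0)
    return _stft.istft(spectrum * gain, geom, n_samples)


def denoise(
    sig: AudioSignal,
    target_peak: float = DEFAULT_TARGET_PEAK,
    floor_frac: float = DEFAULT_FLOOR_FRAC,
) -> AudioSignal:
    """Full pre-processing chain: normalize, VAD, subtract, re-normalize.

    Computes the STFT once and shares it between the voice activity
    detector, the noise estimate and the subtraction.
    """
    sig = normalize_amplitude(sig, target_peak)
    geom = _stft.default_geometry(sig.sample_rate)
    spectrum = _stft.stft(sig.samples, geom)
    mask = _mask_from_spectrum(spectrum, geom)
    voiceless = ~mask.is_speech
    if not np.any(voiceless):  # cannot happen (fallback), defensive
        return sig
    noise = NoiseProfile(
        mean_magnitude=np.abs(spectrum[:, voiceless]).mean(axis=1),
        n_frames_used=int(voiceless.sum()),
    )
    samples = _subtract_from_spectrum(spectrum, noise, floor_frac, geom, len(sig))
    cleaned = AudioSignal(samples=samples, sample_rate=sig.sample_rate)
    return normalize_amplitude(cleaned, target_peak)


def _geometry(
    sig: AudioSignal, frame_length: int | None, hop_length: int | None
) -> _stft.StftGeometry:
    geom = _stft.default_geometry(sig.sample_rate)
    if frame_length is not None or hop_length is not None:
        frame_length = frame_length if frame_length is not None else geom.frame_length
        hop_length = hop_length if hop_length is not None else geom.hop_length
        if hop_length <= 0 or frame_length < hop_length:
            raise ParameterError("need frame_length >= hop_length > 0")
        geom = _stft.StftGeometry(
            sample_rate=sig.sample_rate,
            frame_length=frame_length,
            hop_length=hop_length,
        )
    return geom
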