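"""Package-wide STFT geometry.

One geometry is shared by the denoiser and the prosodic features so that
voicing masks, noise profiles and spectrograms index the same frames:
25 ms Hann window, 10 ms hop (400 / 160 samples at the 16 kHz canonical
rate), one-sided spectrum. Frames are centered at ``p * hop`` samples,
following :class:`scipy.signal.ShortTimeFFT` slicing.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

from .errors import InputError

FRAME_MS = 25.0
HOP_MS = 10.0


@dataclass(frozen=True)
class StftGeometry:
    """Frame length, hop and sample rate of the shared STFT grid."""

    sample_rate: int
    frame_length: int
    hop_length: int

    @property
    def frame_rate(self) -> float:
        """Frames per second of the hop grid."""
        return self.sample_rate / self.hop_length

    def n_frames(self, n_samples: int) -> int:
        """Number of STFT frames produced for a signal of ``n_samples``."""
        sft = _transformer(self)
        return sft.p_max(n_samples) - sft.p_min


def default_geometry(sample_rate: int) -> StftGeometry:
    """25 ms frame / 10 ms hop geometry at ``sample_rate``."""
    return StftGeometry(
        sample_rate=sample_rate,
        frame_length=int(round(FRAME_MS / 1000.0 * sample_rate)),
        hop_length=int(round(HOP_MS / 1000.0 * sample_rate)),
    )


@lru_cache(maxsize=8)
def _transformer(geom: StftGeometry) -> ShortTimeFFT:
    win = hann(geom.frame_length, sym=False)
    return ShortTimeFFT(
        win, hop=geom.hop_length, fs=geom.sample_rate, fft_mode="onesided"
    )


def _phase_factor(geom: StftGeometry) -> np.ndarray:
    # ShortTimeFFT (phase_shift=0) references phase to the window center;
    # a plain rfft of the slice differs by exp(2i*pi*k*m_mid/mfft) per bin
    mfft = geom.frame_length
    k = np.arange(mfft // 2 + 1)
    return np.exp(2j * np.pi * k * (mfft // 2) / mfft)


def stft(samples: np.ndarray, geom: StftGeometry) -> np.ndarray:
    """Complex one-sided STFT, shape (n_bins, n_frames).

    Vectorized equivalent of :meth:`scipy.signal.ShortTimeFFT.stft` for
    this geometry (same slicing and phase convention, batched rfft).
    """
    if samples.size < geom.frame_length:
        raise InputError(
            f"signal of {samples.size} samples is shorter than one "
            f"{geom.frame_length}-sample analysis frame"
        )
    sft = _transformer(geom)
    mfft, hop = geom.frame_length, geom.hop_length
    m_mid = mfft // 2
    p_min, p_max = sft.p_min, sft.p_max(samples.size)
    n_frames = p_max - p_min
    pad_left = m_mid - p_min * hop
    last_end = (p_max - 1) * hop - m_mid + pad_left + mfft
    pad_right = max(0, last_end - (samples.size + pad_left))
    padded = np.concatenate(
        [np.zeros(pad_left), samples, np.zeros(pad_right)]
    )
    frames = np.lib.stride_tricks.sliding_window_view(padded, mfft)[::hop][:n_frames]
    spectrum = np.fft.rfft(frames * sft.win, axis=1).T
    return spectrum * _phase_factor(geom)[:, None]


def istft(spectrum: np.ndarray, geom: StftGeometry, n_samples: int) -> np.ndarray:
    """Inverse STFT truncated/padded to ``n_samples`` (vectorized OLA)."""
    sft = _transformer(geom)
    mfft, hop = geom.frame_length, geom.hop_length
    m_mid = mfft // 2
    slices = np.fft.irfft(
        spectrum / _phase_factor(geom)[:, None], n=mfft, axis=0
    ) * sft.dual_win[:, None]
    p_min = sft.p_min
    out = np.zeros(n_samples + 2 * mfft)  # slack for edge frames
    offset = mfft  # index of sample 0 in the slack buffer
    for p in range(spectrum.shape[1]):
        start = offset + (p + p_min) * hop - m_mid
        out[start : start + mfft] += slices[:, p]
    return out[offset : offset + n_samples]


def bin_frequencies(geom: StftGeometry) -> np.ndarray:
    """Center frequency (Hz) of each one-sided STFT bin."""
    return _transformer(geom).f.copy()


def frame_times(geom: StftGeometry, n_samples: int) -> np.ndarray:
    """Center time (s) of each STFT frame for a signal of ``n_samples``."""
    return _transformer(geom).t(n_samples).copy()


def frame_rms(spectrum: np.ndarray, geom: StftGeometry) -> np.ndarray:
    """Windowed per-frame RMS recovered from STFT magnitudes via Parseval.

    For a one-sided spectrum of an ``mfft``-point real FFT, the windowed
    frame energy is ``(|X_0|^2 + 2*sum(|X_mid|^2) + |X_nyq|^2) / mfft``;
    the RMS is normalized by the window's RMS so a constant full-scale
    input maps to ~its amplitude.
    """
    mag2 = np.abs(spectrum) ** 2
    weights = np.full(mag2.shape[0], 2.0)
    weights[0] = 1.0
    if geom.frame_length % 2 == 0:  # Nyquist bin present
        weights[-1] = 1.0
    energy = (weights[:, None] * mag2).sum(axis=0) / geom.frame_length
    win = hann(geom.frame_length, sym=False)
    return np.sqrt(energy / np.sum(win**2))
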