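"""Prosodic features: spectral timbre descriptors and rhythm features.

Per task recording, 39 named features are computed:

* 21 spectral: six per-frame descriptors of the STFT magnitude
  (centroid, bandwidth, 85% rolloff, flatness, flux, rms) summarized by
  mean/SD/IQR over frames, plus rms dynamic range (P95-P5), the
  least-squares slope of the centroid over time, and the P90 of flux.
* 11 rhythm aggregates from the Fourier and autocorrelation tempograms of
  the onset envelope, and from the envelope itself.
* 7 dedicated tempo features: peak tempo and salience of the time-averaged
  Fourier tempogram in the word (0.5-2 Hz), syllable (2-8 Hz) and
  sub-syllable (8-30 Hz) modulation bands, plus the pause ratio.

Across the three tasks (free speech, counting, PATA) this yields the 117
prosodic columns of the full feature vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.signal.windows import hann

from . import _stft
from .audio_io import AudioSignal
from .errors import ConsistencyError, InputError, ParameterError

logger = logging.getLogger(__name__)

# Tempogram geometry: 4 s windows hopped by 0.5 s on the 100 Hz envelope
# grid resolve 0.25 Hz tempo bins inside a 10 s recording.
TEMPOGRAM_WINDOW_S = 4.0
TEMPOGRAM_HOP_S = 0.5
TEMPO_MIN_HZ = 0.25
TEMPO_MAX_HZ = 30.0

# Modulation-rate bands (Hz) for word / syllable / sub-syllable tempo.
WORD_BAND = (0.5, 2.0)
SYLLABLE_BAND = (2.0, 8.0)
SUBSYLLABLE_BAND = (8.0, 30.0)

_SPECTRAL_DESCRIPTORS = ("centroid", "bandwidth", "rolloff85", "flatness", "flux", "rms")
_STATS = ("mean", "sd", "iqr")

RHYTHM_FEATURES = (
    "mean_rhythmicity",
    "rhythmicity_cv",
    "dominant_rate_hz",
    "dominant_salience",
    "ac_dominant_rate_hz",
    "ac_dominant_salience",
    "ac_tempo_entropy",
    "ac_rate_sd",
    "onset_rate_hz",
    "onset_strength_mean",
    "onset_strength_cv",
)

BAND_TEMPO_FEATURES = (
    "word_tempo_hz",
    "word_salience",
    "syllable_tempo_hz",
    "syllable_salience",
    "subsyllable_tempo_hz",
    "subsyllable_salience",
    "pause_ratio",
)

#: Ordered names of the 39 per-task prosodic features.
PROSODIC_FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"{d}_{s}" for d in _SPECTRAL_DESCRIPTORS for s in _STATS)
    + ("rms_dynamic_range", "centroid_slope", "flux_p90")
    + RHYTHM_FEATURES
    + BAND_TEMPO_FEATURES
)


@dataclass(frozen=True)
class Spectrogram:
    """STFT magnitudes on the package-wide 25 ms / 10 ms grid."""

    magnitudes: np.ndarray  # (n_bins, n_frames), >= 0
    bin_frequencies: np.ndarray  # Hz per bin
    frame_times: np.ndarray  # s per frame
    geom: _stft.StftGeometry

    @property
    def n_frames(self) -> int:
        return self.magnitudes.shape[1]


@dataclass(frozen=True)
class OnsetEnvelope:
    """Frame-wise measure of spectral-energy increase."""

    values: np.ndarray  # >= 0, one per frame
    frame_rate: float  # frames per second

    @property
    def duration_s(self) -> float:
        return self.values.size / self.frame_rate


@dataclass(frozen=True)
class Tempogram:
    """Time-tempo representation of an onset envelope."""

    kind: str  # "fourier" | "autocorrelation"
    values: np.ndarray  # (n_tempo, n_windows)
    tempo_axis: np.ndarray  # events/second per row, strictly increasing

    def time_average(self) -> np.ndarray:
        return self.values.mean(axis=1)


def compute_spectrogram(sig: AudioSignal) -> Spectrogram:
    """|STFT| with 25 ms Hann frames and 10 ms hop."""
    geom = _stft.default_geometry(sig.sample_rate)
    spectrum = _stft.stft(sig.samples, geom)
    return Spectrogram(
        magnitudes=np.abs(spectrum),
        bin_frequencies=_stft.bin_frequencies(geom),
        frame_times=_stft.frame_times(geom, len(sig)),
        geom=geom,
    )


def spectral_descriptors(spec: Spectrogram) -> dict[str, np.ndarray]:
    """Per-frame centroid, bandwidth, rolloff85, flatness, flux and rms.

    Frames with zero total magnitude yield centroid 0, flatness 1 and 0 for
    the remaining descriptors.
    """
    mag = spec.magnitudes
    freqs = spec.bin_frequencies
    total = mag.sum(axis=0)
    nonzero = total > 0
    safe_total = np.where(nonzero, total, 1.0)

    centroid = np.where(nonzero, (freqs[:, None] * mag).sum(axis=0) / safe_total, 0.0)
    dev2 = (freqs[:, None] - centroid[None, :]) ** 2
    bandwidth = np.where(nonzero, np.sqrt((dev2 * mag).sum(axis=0) / safe_total), 0.0)

    cum = np.cumsum(mag, axis=0)
    reached = cum >= 0.85 * total[None, :]
    rolloff_idx = reached.argmax(axis=0)
    rolloff = np.where(nonzero, freqs[rolloff_idx], 0.0)

    power = mag**2
    amin = 1e-10
    flatness = np.exp(np.mean(np.log(power + amin), axis=0)) / (
        np.mean(power, axis=0) + amin
    )

    inc = np.clip(np.diff(mag, axis=1), 0.0, None)
    flux = np.concatenate([[0.0], np.sqrt((inc**2).sum(axis=0))])

    rms = _stft.frame_rms(mag.astype(np.complex128), spec.geom)

    return {
        "centroid": centroid,
        "bandwidth": bandwidth,
        "rolloff85": rolloff,
        "flatness": flatness,
        "flux": flux,
        "rms": rms,
    }


def onset_envelope(spec: Spectrogram) -> OnsetEnvelope:
    """Half-wave-rectified first difference of log(1+magnitude), bin-summed."""
    if spec.n_frames < 2:
        raise InputError("onset envelope needs at least two spectrogram frames")
    logmag = np.log1p(spec.magnitudes)
    inc = np.clip(np.diff(logmag, axis=1), 0.0, None).sum(axis=0)
    values = np.concatenate([[0.0], inc])
    return OnsetEnvelope(values=values, frame_rate=spec.geom.frame_rate)


def _tempogram_windows(env: OnsetEnvelope, window_s: float) -> tuple[int, int, int]:
    win_len = int(round(window_s * env.frame_rate))
    hop = max(1, int(round(TEMPOGRAM_HOP_S * env.frame_rate)))
    if env.values.size < win_len:
        raise InputError(
            f"envelope of {env.duration_s:.2f} s is shorter than the "
            f"{window_s:.2f} s tempogram window; use a shorter window"
        )
    n_windows = 1 + (env.values.size - win_len) // hop
    return win_len, hop, n_windows


def fourier_tempogram(
    env: OnsetEnvelope, window_s: float = TEMPOGRAM_WINDOW_S
) -> Tempogram:
    """Magnitude STFT of the onset envelope, restricted to 0.25-30 Hz.

    Each window is mean-subtracted and Hann-weighted before the DFT so the
    envelope's DC level does not leak into the slow word-rate bins.
    """
    win_len, hop, n_windows = _tempogram_windows(env, window_s)
    freqs = np.fft.rfftfreq(win_len, d=1.0 / env.frame_rate)
    keep = (freqs >= TEMPO_MIN_HZ) & (freqs <= TEMPO_MAX_HZ)
    window = hann(win_len, sym=False)
    values = np.empty((int(keep.sum()), n_windows))
    for w in range(n_windows):
        seg = env.values[w * hop : w * hop + win_len]
        seg = (seg - seg.mean()) * window
        values[:, w] = np.abs(np.fft.rfft(seg))[keep]
    return Tempogram(kind="fourier", values=values, tempo_axis=freqs[keep])


def autocorr_tempogram(
    env: OnsetEnvelope, window_s: float = TEMPOGRAM_WINDOW_S
) -> Tempogram:
    """Windowed, lag-normalized autocorrelation on an events/second axis.

    Per window the mean is removed, the biased autocorrelation is computed
    and normalized by its lag-0 value; lags are mapped to tempo
    ``frame_rate / lag`` and restricted to 0.25-30 Hz (rows sorted by
    increasing tempo).
    """
    win_len, hop, n_windows = _tempogram_windows(env, window_s)
    lags = np.arange(1, win_len)
    tempo = env.frame_rate / lags
    keep = (tempo >= TEMPO_MIN_HZ) & (tempo <= TEMPO_MAX_HZ)
    lags = lags[keep]
    order = np.argsort(tempo[keep])
    values = np.empty((lags.size, n_windows))
    for w in range(n_windows):
        seg = env.values[w * hop : w * hop + win_len]
        seg = seg - seg.mean()
        full = np.correlate(seg, seg, mode="full")[win_len - 1 :] / win_len
        if full[0] > 0:
            values[:, w] = (full[lags] / full[0])[order]
        else:
            values[:, w] = 0.0
    return Tempogram(
        kind="autocorrelation", values=values, tempo_axis=env.frame_rate / lags[order]
    )


def rhythm_aggregates(
    tg_f: Tempogram, tg_ac: Tempogram, env: OnsetEnvelope
) -> dict[str, float]:
    """Eleven aggregates of rhythmicity strength, rate and variability."""
    if tg_f.kind != "fourier" or tg_ac.kind != "autocorrelation":
        raise ConsistencyError("expected one fourier and one autocorrelation tempogram")
    out: dict[str, float] = {name: 0.0 for name in RHYTHM_FEATURES}
    if not np.any(env.values > 0):
        logger.warning("rhythm_aggregates: degenerate all-zero envelope")
        return out

    per_window_max = tg_f.values.max(axis=0)
    m = per_window_max.mean()
    out["mean_rhythmicity"] = float(m)
    out["rhythmicity_cv"] = float(per_window_max.std() / m) if m > 0 else 0.0
    avg_f = tg_f.time_average()
    if avg_f.max() > 0:
        out["dominant_rate_hz"] = float(tg_f.tempo_axis[int(avg_f.argmax())])
        out["dominant_salience"] = float(avg_f.max() / avg_f.mean())

    avg_ac = np.clip(tg_ac.time_average(), 0.0, None)
    if avg_ac.max() > 0:
        out["ac_dominant_rate_hz"] = float(tg_ac.tempo_axis[int(avg_ac.argmax())])
        out["ac_dominant_salience"] = float(avg_ac.max() / avg_ac.mean())
        p = avg_ac / avg_ac.sum()
        nz = p[p > 0]
        out["ac_tempo_entropy"] = float(-(nz * np.log(nz)).sum())
    window_peaks = []
    for w in range(tg_ac.values.shape[1]):
        col = tg_ac.values[:, w]
        if col.max() > 0:
            window_peaks.append(tg_ac.tempo_axis[int(col.argmax())])
    if len(window_peaks) >= 2:
        out["ac_rate_sd"] = float(np.std(window_peaks))

    p90 = np.percentile(env.values, 90.0)
    peaks, _ = find_peaks(env.values, height=0.5 * p90)
    out["onset_rate_hz"] = float(peaks.size / env.duration_s)
    mean_strength = env.values.mean()
    out["onset_strength_mean"] = float(mean_strength)
    out["onset_strength_cv"] = (
        float(env.values.std() / mean_strength) if mean_strength > 0 else 0.0
    )
    return out


def band_tempo_features(tg_f: Tempogram, env: OnsetEnvelope) -> dict[str, float]:
    """Peak tempo/salience per modulation band, plus the pause ratio.

    The Fourier tempogram is averaged over time; within the word, syllable
    and sub-syllable bands the peak location (Hz) and its salience
    (peak / band mean) are reported. Bands with no positive content report
    0 for both. ``pause_ratio`` is the fraction of envelope frames below
    10% of the envelope's P90.
    """
    if tg_f.kind != "fourier":
        raise ConsistencyError("band tempo features require a fourier tempogram")
    avg = tg_f.time_average()
    out: dict[str, float] = {}
    for name, (lo, hi) in (
        ("word", WORD_BAND),
        ("syllable", SYLLABLE_BAND),
        ("subsyllable", SUBSYLLABLE_BAND),
    ):
        in_band = (tg_f.tempo_axis >= lo) & (tg_f.tempo_axis <= hi)
        band = avg[in_band]
        if band.size and band.max() > 0:
            idx = int(band.argmax())
            out[f"{name}_tempo_hz"] = float(tg_f.tempo_axis[in_band][idx])
            out[f"{name}_salience"] = float(band.max() / band.mean())
        else:
            out[f"{name}_tempo_hz"] = 0.0
            out[f"{name}_salience"] = 0.0
    p90 = np.percentile(env.values, 90.0)
    # strict < makes the all-zero envelope report 0, matching the other bands
    out["pause_ratio"] = float(np.mean(env.values < 0.1 * p90))
    return out


def _iqr(x: np.ndarray) -> float:
    q75, q25 = np.percentile(x, [75.0, 25.0])
    return float(q75 - q25)


def prosodic_vector(sig: AudioSignal) -> dict[str, float]:
    """The 39 named prosodic features of one (preprocessed) task recording."""
    spec = compute_spectrogram(sig)
    desc = spectral_descriptors(spec)

    features: dict[str, float] = {}
    for name in _SPECTRAL_DESCRIPTORS:
        series = desc[name]
        features[f"{name}_mean"] = float(series.mean())
        features[f"{name}_sd"] = float(series.std())
        features[f"{name}_iqr"] = _iqr(series)
    features["rms_dynamic_range"] = float(
        np.percentile(desc["rms"], 95.0) - np.percentile(desc["rms"], 5.0)
    )
    if np.any(desc["centroid"] != desc["centroid"][0]):
        slope = np.polyfit(spec.frame_times, desc["centroid"], 1)[0]
    else:
        slope = 0.0
    features["centroid_slope"] = float(slope)
    features["flux_p90"] = float(np.percentile(desc["flux"], 90.0))

    env = onset_envelope(spec)
    tg_f = fourier_tempogram(env)
    tg_ac = autocorr_tempogram(env)
    features.update(rhythm_aggregates(tg_f, tg_ac, env))
    features.update(band_tempo_features(tg_f, env))

    assert set(features) == set(PROSODIC_FEATURE_NAMES)
    if not all(np.isfinite(v) for v in features.values()):
        raise ParameterError("non-finite prosodic feature computed")
    return {name: features[name] for name in PROSODIC_FEATURE_NAMES}
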