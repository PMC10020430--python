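"""Severity-parameterized synthetic speech cohorts.

Generates recording sets (free speech, counting, PATA syllable repetition)
plus sidecar transcripts whose acoustic and lexical structure degrades
monotonically with an integer severity label 0-5: slower and more
irregular syllable trains, loudness spikes, more noise, lower word
probabilities, and more pausing. The mapping from severity to synthesis
parameters is a documented test harness, not a clinical claim; every
constant is overridable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .audio_io import CANONICAL_RATE, AudioSignal, write_wav
from .errors import ParameterError
from .lexical import (
    GERMAN_NUMERALS,
    Transcript,
    TranscriptWord,
    save_transcript,
)

logger = logging.getLogger(__name__)

#: Default severity label weights: median 2, IQR 1-3, mirroring a cohort
#: concentrated in the mild-to-moderate range.
DEFAULT_LABEL_WEIGHTS = {0: 0.08, 1: 0.22, 2: 0.30, 3: 0.22, 4: 0.12, 5: 0.06}

PATA_DURATION_S = 10.0
FREE_SPEECH_DURATION_S = 30.0
TASKS = ("free", "count", "pata")

_BETA_CONCENTRATION = 20.0
_F0_HZ = 120.0
_SYLLABLE_BURST_S = 0.030
_SYLLABLE_VOWEL_S = 0.120

# Words used by the free-speech generator (all in the built-in word list).
_FREE_SPEECH_WORDS = (
    "ich", "gehe", "gerne", "und", "dann", "lese", "viel", "im", "garten",
    "arbeite", "koche", "mit", "meiner", "familie", "spiele", "musik",
    "jeden", "tag", "wandern", "schwimmen", "freunde", "treffen",
)
_PSEUDO_SYLLABLES = ("bla", "kro", "zim", "fep", "glu", "tra", "vop", "dri")

# Rough syllable counts of the numeral words (eins..zehn).
_NUMERAL_SYLLABLES = {
    "eins": 1, "zwei": 1, "drei": 1, "vier": 1, "fünf": 1,
    "sechs": 1, "sieben": 2, "acht": 1, "neun": 1, "zehn": 1,
}


@dataclass(frozen=True)
class SeverityProfile:
    """Synthesis parameters encoding one severity grade."""

    severity: int
    pata_rate_hz: float  # mean syllable rate of the PATA train
    interval_cv: float  # log-normal jitter of inter-syllable intervals
    spike_prob: float  # per-syllable probability of a +6 dB loudness spike
    snr_db: float  # additive white-noise SNR
    word_prob_mean: float  # mean per-word transcript probability
    pause_rate: float  # pauses per second in free speech

    def __post_init__(self) -> None:
        if self.pata_rate_hz <= 0:
            raise ParameterError("pata_rate_hz must be > 0")
        if self.interval_cv < 0:
            raise ParameterError("interval_cv must be >= 0")
        if not 0.0 <= self.spike_prob <= 1.0:
            raise ParameterError("spike_prob must be in [0, 1]")
        if not 0.0 <= self.word_prob_mean <= 1.0:
            raise ParameterError("word_prob_mean must be in [0, 1]")


def severity_profile(severity: int, **overrides) -> SeverityProfile:
    """Default severity -> parameter map (linear degradations)."""
    if not 0 <= severity <= 5:
        raise ParameterError(f"severity must be in 0-5, got {severity}")
    profile = SeverityProfile(
        severity=severity,
        pata_rate_hz=6.0 * (1.0 - 0.12 * severity),
        interval_cv=0.03 + 0.06 * severity,
        spike_prob=0.02 * severity,
        snr_db=30.0 - 2.0 * severity,
        word_prob_mean=max(0.2, 0.95 - 0.12 * severity),
        pause_rate=0.05 * severity,
    )
    return replace(profile, **overrides) if overrides else profile


def _resonator(x: np.ndarray, freq_hz: float, bandwidth_hz: float, sr: int) -> np.ndarray:
    r = np.exp(-np.pi * bandwidth_hz / sr)
    theta = 2.0 * np.pi * freq_hz / sr
    return lfilter([1.0 - r], [1.0, -2.0 * r * np.cos(theta), r * r], x)


_VOWEL_CACHE: dict[tuple[float, float, int], np.ndarray] = {}


def _vowel(formants: tuple[float, float], sr: int) -> np.ndarray:
    """Deterministic 120 ms two-formant vowel (cached; rng-free)."""
    key = (formants[0], formants[1], sr)
    if key not in _VOWEL_CACHE:
        n_vowel = int(_SYLLABLE_VOWEL_S * sr)
        t = np.arange(n_vowel) / sr
        harmonics = np.arange(1, int(0.45 * sr / _F0_HZ))
        source = (
            np.sin(2.0 * np.pi * _F0_HZ * np.outer(harmonics, t)) / harmonics[:, None]
        ).sum(axis=0)
        vowel = _resonator(source, formants[0], 90.0, sr)
        vowel = _resonator(vowel, formants[1], 120.0, sr)
        env = np.minimum(1.0, np.minimum(t / 0.01, (t[-1] - t) / 0.03))
        vowel = vowel * env
        peak = np.max(np.abs(vowel))
        if peak > 0:
            vowel = vowel / peak * 0.8
        _VOWEL_CACHE[key] = vowel
    return _VOWEL_CACHE[key]


def _synth_syllable(rng: np.random.Generator, formants: tuple[float, float],
                    sr: int = CANONICAL_RATE) -> np.ndarray:
    """One syllable: 30 ms noise burst (consonant) + 120 ms two-formant vowel."""
    n_burst = int(_SYLLABLE_BURST_S * sr)
    burst = rng.standard_normal(n_burst) * np.hanning(n_burst) * 0.4
    return np.concatenate([burst, _vowel(formants, sr)])


def _jittered_intervals(
    rng: np.random.Generator, mean_s: float, cv: float, n: int
) -> np.ndarray:
    """Log-normal intervals with the requested mean and CV."""
    if cv <= 0:
        return np.full(n, mean_s)
    sigma2 = np.log(1.0 + cv * cv)
    mu = np.log(mean_s) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def _add_noise(
    samples: np.ndarray, snr_db: float, rng: np.random.Generator
) -> np.ndarray:
    signal_rms = np.sqrt(np.mean(samples**2))
    if signal_rms == 0:
        return samples
    noise_rms = signal_rms / (10.0 ** (snr_db / 20.0))
    return samples + rng.standard_normal(samples.size) * noise_rms


def _word_probability(rng: np.random.Generator, mean: float) -> float:
    a = mean * _BETA_CONCENTRATION
    b = (1.0 - mean) * _BETA_CONCENTRATION
    return float(np.clip(rng.beta(a, b), 0.0, 1.0))


def _place(canvas: np.ndarray, unit: np.ndarray, start_idx: int) -> None:
    stop = min(start_idx + unit.size, canvas.size)
    if stop > start_idx >= 0:
        canvas[start_idx:stop] += unit[: stop - start_idx]


def synth_syllable_train(
    profile: SeverityProfile,
    duration_s: float = PATA_DURATION_S,
    seed: int = 0,
) -> tuple[AudioSignal, Transcript]:
    """A PATA-style train of alternating syllables with jitter and spikes.

    Syllables occur at mean rate ``profile.pata_rate_hz`` (syllables per
    second; a "pata" word covers two syllables) with log-normal interval
    jitter; each syllable may get a +6 dB gain spike with probability
    ``spike_prob``; white noise is added at ``snr_db``.
    """
    if duration_s <= 0:
        raise ParameterError("duration_s must be > 0")
    sr = CANONICAL_RATE
    rng = np.random.default_rng(seed)
    canvas = np.zeros(int(duration_s * sr))

    mean_interval = 1.0 / profile.pata_rate_hz
    n_max = int(duration_s / mean_interval * 2) + 8
    intervals = _jittered_intervals(rng, mean_interval, profile.interval_cv, n_max)
    onsets = 0.05 + np.cumsum(np.concatenate([[0.0], intervals[:-1]]))
    onsets = onsets[onsets < duration_s - _SYLLABLE_BURST_S]

    formant_pairs = ((700.0, 1100.0), (400.0, 1800.0))  # "pa", "ta"
    syllable_times: list[float] = []
    for i, onset in enumerate(onsets):
        unit = _synth_syllable(rng, formant_pairs[i % 2], sr)
        if rng.random() < profile.spike_prob:
            unit = unit * 2.0  # +6 dB
        _place(canvas, unit, int(onset * sr))
        syllable_times.append(float(onset))

    samples = _add_noise(canvas, profile.snr_db, rng)

    words = []
    unit_s = _SYLLABLE_BURST_S + _SYLLABLE_VOWEL_S
    for j in range(0, len(syllable_times) - 1, 2):
        words.append(
            TranscriptWord(
                text="pata",
                start_s=syllable_times[j],
                end_s=min(syllable_times[j + 1] + unit_s, duration_s),
                probability=_word_probability(rng, profile.word_prob_mean),
            )
        )
    return (
        AudioSignal(samples=samples, sample_rate=sr),
        Transcript(words=tuple(words)),
    )


def _synth_word(
    rng: np.random.Generator, n_syllables: int, profile: SeverityProfile,
) -> np.ndarray:
    """A word as a group of syllables with jittered intra-word spacing."""
    sr = CANONICAL_RATE
    formant_bank = ((700.0, 1100.0), (400.0, 1800.0), (300.0, 2300.0), (500.0, 1500.0))
    gap = _jittered_intervals(rng, 0.16, profile.interval_cv, n_syllables)
    pieces: list[np.ndarray] = []
    for k in range(n_syllables):
        unit = _synth_syllable(rng, formant_bank[rng.integers(len(formant_bank))], sr)
        if rng.random() < profile.spike_prob:
            unit = unit * 2.0
        pieces.append(unit)
        if k < n_syllables - 1:
            pieces.append(np.zeros(int(max(0.0, gap[k] - 0.15) * sr)))
    return np.concatenate(pieces)


def synth_counting(
    profile: SeverityProfile, seed: int = 0
) -> tuple[AudioSignal, Transcript]:
    """Counting one to ten and back: 20 numeral words."""
    sr = CANONICAL_RATE
    rng = np.random.default_rng(seed)
    sequence = GERMAN_NUMERALS + GERMAN_NUMERALS[::-1]

    base_gap = 0.35 * (1.0 + 0.15 * profile.severity)
    gaps = _jittered_intervals(rng, base_gap, profile.interval_cv, len(sequence))

    pieces: list[np.ndarray] = [np.zeros(int(0.2 * sr))]
    words: list[TranscriptWord] = []
    cursor_s = 0.2
    for token, gap in zip(sequence, gaps):
        unit = _synth_word(rng, _NUMERAL_SYLLABLES[token], profile)
        pieces.append(unit)
        words.append(
            TranscriptWord(
                text=token,
                start_s=cursor_s,
                end_s=cursor_s + unit.size / sr,
                probability=_word_probability(rng, profile.word_prob_mean),
            )
        )
        cursor_s += unit.size / sr + gap
        pieces.append(np.zeros(int(gap * sr)))
    pieces.append(np.zeros(int(0.2 * sr)))
    samples = _add_noise(np.concatenate(pieces), profile.snr_db, rng)
    return (
        AudioSignal(samples=samples, sample_rate=sr),
        Transcript(words=tuple(words)),
    )


def synth_free_speech(
    profile: SeverityProfile,
    duration_s: float = FREE_SPEECH_DURATION_S,
    seed: int = 0,
) -> tuple[AudioSignal, Transcript]:
    """A free word stream with pauses and a severity-driven non-word share."""
    if duration_s < 4.0:
        raise ParameterError("free speech must be at least a few seconds long")
    sr = CANONICAL_RATE
    rng = np.random.default_rng(seed)
    nonword_frac = min(0.5, 0.04 + 0.08 * profile.severity)
    # convert pauses/second into a per-word pause probability via the mean
    # word period (~0.8 s including gaps)
    p_pause = min(0.8, profile.pause_rate * 0.8)

    pieces: list[np.ndarray] = [np.zeros(int(0.2 * sr))]
    words: list[TranscriptWord] = []
    cursor_s = 0.2
    while cursor_s < duration_s:
        if rng.random() < nonword_frac:
            n_syll = int(rng.integers(1, 4))
            token = "".join(
                _PSEUDO_SYLLABLES[rng.integers(len(_PSEUDO_SYLLABLES))]
                for _ in range(max(2, n_syll))
            )
        else:
            token = _FREE_SPEECH_WORDS[rng.integers(len(_FREE_SPEECH_WORDS))]
            n_syll = min(4, max(1, (len(token) + 2) // 3))
        unit = _synth_word(rng, n_syll, profile)
        pieces.append(unit)
        words.append(
            TranscriptWord(
                text=token,
                start_s=cursor_s,
                end_s=cursor_s + unit.size / sr,
                probability=_word_probability(rng, profile.word_prob_mean),
            )
        )
        cursor_s += unit.size / sr
        gap = float(_jittered_intervals(rng, 0.18, max(profile.interval_cv, 0.1), 1)[0])
        if rng.random() < p_pause:
            gap += float(rng.uniform(0.4, 1.2))
        pieces.append(np.zeros(int(gap * sr)))
        cursor_s += gap
    pieces.append(np.zeros(int(0.2 * sr)))
    samples = np.concatenate(pieces)
    if samples.size < int(duration_s * sr):  # pad to the requested length
        samples = np.concatenate(
            [samples, np.zeros(int(duration_s * sr) - samples.size)]
        )
    samples = _add_noise(samples, profile.snr_db, rng)
    return (
        AudioSignal(samples=samples, sample_rate=sr),
        Transcript(words=tuple(words)),
    )


def draw_labels(
    n_subjects: int,
    rng: np.random.Generator,
    label_weights: dict[int, float] | None = None,
    one_per_label: bool = False,
) -> np.ndarray:
    """Severity labels for a cohort; weighted draw or forced one-per-label."""
    if one_per_label:
        if n_subjects < len(DEFAULT_LABEL_WEIGHTS):
            raise ParameterError("one_per_label needs n_subjects >= 6")
        return np.array([i % 6 for i in range(n_subjects)], dtype=int)
    weights = label_weights or DEFAULT_LABEL_WEIGHTS
    labels = np.array(sorted(weights), dtype=int)
    probs = np.array([weights[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(labels, size=n_subjects, p=probs)


def generate_assessment(
    severity: int, seed: int, free_duration_s: float = FREE_SPEECH_DURATION_S
) -> dict[str, tuple[AudioSignal, Transcript]]:
    """One recording set (all three tasks) at the given severity."""
    profile = severity_profile(severity)
    seq = np.random.SeedSequence(entropy=seed)
    s_free, s_count, s_pata = [int(s.generate_state(1)[0]) for s in seq.spawn(3)]
    return {
        "free": synth_free_speech(profile, free_duration_s, seed=s_free),
        "count": synth_counting(profile, seed=s_count),
        "pata": synth_syllable_train(profile, PATA_DURATION_S, seed=s_pata),
    }


def generate_cohort(
    out_dir: str | Path,
    n_subjects: int,
    seed: int = 0,
    label_weights: dict[int, float] | None = None,
    one_per_label: bool = False,
    free_duration_s: float = FREE_SPEECH_DURATION_S,
) -> pd.DataFrame:
    """Write a full synthetic cohort to ``out_dir``; returns the manifest.

    Layout: ``<subject>/<task>.wav`` + ``<task>.transcript.json`` per
    assessment, plus ``manifest.tsv`` (subject_id, task, wav_path,
    transcript_path, label) and ``labels.tsv`` (subject_id, label).
    Fully deterministic given the seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    labels = draw_labels(n_subjects, rng, label_weights, one_per_label)

    rows = []
    for i, label in enumerate(labels):
        subject = f"synth{i:04d}"
        subject_dir = out_dir / subject
        subject_dir.mkdir(exist_ok=True)
        subject_seed = int(np.random.SeedSequence(entropy=(seed, i)).generate_state(1)[0])
        assessment = generate_assessment(int(label), subject_seed, free_duration_s)
        for task in TASKS:
            sig, transcript = assessment[task]
            wav_path = subject_dir / f"{task}.wav"
            json_path = subject_dir / f"{task}.transcript.json"
            write_wav(wav_path, sig)
            save_transcript(json_path, transcript)
            rows.append(
                {
                    "subject_id": subject,
                    "task": task,
                    "wav_path": str(wav_path.relative_to(out_dir)),
                    "transcript_path": str(json_path.relative_to(out_dir)),
                    "label": int(label),
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    labels_df = pd.DataFrame(
        {"subject_id": [f"synth{i:04d}" for i in range(n_subjects)],
         "label": labels.astype(int)}
    )
    labels_df.to_csv(out_dir / "labels.tsv", sep="\t", index=False)
    logger.info("wrote %d synthetic assessments to %s", n_subjects, out_dir)
    return manifest
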