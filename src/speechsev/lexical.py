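"""Lexical features from per-word transcripts with probabilities.

Transcription itself is behind a pluggable :class:`Transcriber` contract;
the package ships a :class:`SidecarTranscriber` that reads per-recording
JSON sidecar files (the form produced by the synthetic cohort generator).
From a transcript, 8 features per task are computed: detected and real word
rates, their ratio, word-duration mean/SD, and the mean/SD/min of the
per-word probabilities. The mean probability is the transcript's
confidence (intelligibility) score. Across three tasks this yields the 24
lexical columns of the full feature vector.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np

from .audio_io import AudioSignal
from .errors import CapabilityError, ParameterError

logger = logging.getLogger(__name__)

#: Ordered names of the 8 per-task lexical features.
LEXICAL_FEATURE_NAMES: tuple[str, ...] = (
    "detected_word_rate",
    "real_word_rate",
    "real_word_ratio",
    "word_duration_mean_s",
    "word_duration_sd_s",
    "confidence_mean",
    "confidence_sd",
    "confidence_min",
)

# German numerals (the counting task) plus a few high-frequency words, so
# synthetic free speech has an in-dictionary vocabulary out of the box.
GERMAN_NUMERALS = (
    "eins", "zwei", "drei", "vier", "fünf",
    "sechs", "sieben", "acht", "neun", "zehn",
)
_COMMON_WORDS = (
    "ich", "gehe", "gerne", "und", "dann", "lese", "viel", "im", "garten",
    "arbeite", "koche", "mit", "meiner", "familie", "spiele", "musik",
    "jeden", "tag", "wandern", "schwimmen", "freunde", "treffen", "hause",
    "morgen", "abend", "oft", "sehr", "auch", "das", "macht", "mir", "freude",
)
DEFAULT_WORDS = GERMAN_NUMERALS + _COMMON_WORDS


@dataclass(frozen=True)
class TranscriptWord:
    text: str
    start_s: float
    end_s: float
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.start_s < self.end_s:
            raise ParameterError(
                f"word times must satisfy 0 <= start < end, got "
                f"[{self.start_s}, {self.end_s}]"
            )
        if not 0.0 <= self.probability <= 1.0:
            raise ParameterError(f"word probability {self.probability} not in [0, 1]")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class Transcript:
    """Ordered words with timings and per-word probabilities."""

    words: tuple[TranscriptWord, ...]
    language_tag: str = "de"

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.words, key=lambda w: w.start_s))
        object.__setattr__(self, "words", ordered)

    def __len__(self) -> int:
        return len(self.words)


@dataclass(frozen=True)
class WordList:
    """Case-insensitive set of valid words."""

    entries: frozenset[str] = field(
        default_factory=lambda: frozenset(DEFAULT_WORDS)
    )

    def __post_init__(self) -> None:
        lowered = frozenset(w.lower() for w in self.entries)
        if not lowered:
            raise ParameterError("WordList must be non-empty")
        object.__setattr__(self, "entries", lowered)

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.entries

    @classmethod
    def from_file(cls, path: str | Path) -> "WordList":
        """Load one word per line (blank lines and '#' comments skipped)."""
        words = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            token = line.strip()
            if token and not token.startswith("#"):
                words.append(token)
        return cls(entries=frozenset(words))


class Transcriber(Protocol):
    """Contract every speech-to-text backend implements."""

    def transcribe(self, sig: AudioSignal, recording_path: Path) -> Transcript: ...


class SidecarTranscriber:
    """Reads ``<recording>.transcript.json`` sidecar files.

    Sidecar format: ``{"language": str, "words": [{"text", "start_s",
    "end_s", "probability"}, ...]}``. Out-of-order words are re-sorted by
    start time by the :class:`Transcript` constructor.
    """

    def transcribe(self, sig: AudioSignal, recording_path: Path) -> Transcript:
        sidecar = sidecar_path(recording_path)
        if not sidecar.exists():
            raise CapabilityError(
                f"no transcript sidecar at {sidecar}; plug in a real "
                "speech-to-text backend for raw recordings"
            )
        return load_transcript(sidecar)


def sidecar_path(recording_path: str | Path) -> Path:
    p = Path(recording_path)
    return p.with_name(p.stem + ".transcript.json")


def load_transcript(path: str | Path) -> Transcript:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    words = tuple(
        TranscriptWord(
            text=w["text"],
            start_s=float(w["start_s"]),
            end_s=float(w["end_s"]),
            probability=float(w["probability"]),
        )
        for w in payload["words"]
    )
    return Transcript(words=words, language_tag=payload.get("language", "de"))


def save_transcript(path: str | Path, transcript: Transcript) -> None:
    payload = {
        "language": transcript.language_tag,
        "words": [
            {
                "text": w.text,
                "start_s": round(w.start_s, 6),
                "end_s": round(w.end_s, 6),
                "probability": round(w.probability, 6),
            }
            for w in transcript.words
        ],
    }
    Path(path).write_text(json.dumps(payload, ensure_ascii=False, indent=1) + "\n",
                          encoding="utf-8")


def confidence_score(transcript: Transcript) -> float:
    """Mean per-word probability; 0 (with a logged flag) if no words.

    No target text is needed: the score is internal to the transcript and
    captures how confidently each word was recognized.
    """
    if len(transcript) == 0:
        logger.warning("confidence_score: empty transcript, reporting 0")
        return 0.0
    return float(np.mean([w.probability for w in transcript.words]))


def word_stats(
    transcript: Transcript, wordlist: WordList, duration_s: float
) -> dict[str, float]:
    """The 8 named lexical features of one task recording.

    Counts are exposed as per-second rates so recordings of different
    lengths are comparable; SDs over fewer than two items are 0.
    """
    if duration_s <= 0:
        raise ParameterError(f"duration_s must be > 0, got {duration_s}")
    if len(transcript) == 0:
        logger.warning("word_stats: empty transcript, reporting zeros")
        return {name: 0.0 for name in LEXICAL_FEATURE_NAMES}

    n_detected = len(transcript)
    n_real = sum(1 for w in transcript.words if w.text in wordlist)
    durations = np.array([w.duration_s for w in transcript.words])
    probs = np.array([w.probability for w in transcript.words])
    return {
        "detected_word_rate": n_detected / duration_s,
        "real_word_rate": n_real / duration_s,
        "real_word_ratio": n_real / n_detected,
        "word_duration_mean_s": float(durations.mean()),
        "word_duration_sd_s": float(durations.std()) if durations.size > 1 else 0.0,
        "confidence_mean": float(probs.mean()),
        "confidence_sd": float(probs.std()) if probs.size > 1 else 0.0,
        "confidence_min": float(probs.min()),
    }


def lexical_vector(
    transcript: Transcript, duration_s: float, wordlist: WordList | None = None
) -> dict[str, float]:
    """``word_stats`` with the built-in word list by default."""
    return word_stats(transcript, wordlist or WordList(), duration_s)
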