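"""Assembly of the full 141-column feature vector per recording set.

Per assessment, each of the three task recordings (free, count, pata)
contributes 39 prosodic and 8 lexical features, named
``<task>__<feature>``: 117 prosodic + 24 lexical = 141 columns.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .audio_io import read_wav, to_canonical
from .errors import InputError
from .lexical import (
    LEXICAL_FEATURE_NAMES,
    SidecarTranscriber,
    Transcriber,
    WordList,
    lexical_vector,
)
from .preprocess import denoise
from .prosodic import PROSODIC_FEATURE_NAMES, prosodic_vector
from .synthetic import TASKS

logger = logging.getLogger(__name__)

PROSODIC_COLUMNS: tuple[str, ...] = tuple(
    f"{task}__{name}" for task in TASKS for name in PROSODIC_FEATURE_NAMES
)
LEXICAL_COLUMNS: tuple[str, ...] = tuple(
    f"{task}__{name}" for task in TASKS for name in LEXICAL_FEATURE_NAMES
)
#: All 141 feature column names in canonical order.
FEATURE_COLUMNS: tuple[str, ...] = PROSODIC_COLUMNS + LEXICAL_COLUMNS


def extract_assessment(
    wav_paths: dict[str, Path],
    transcriber: Transcriber | None = None,
    wordlist: WordList | None = None,
) -> dict[str, float]:
    """Features of one recording set given per-task WAV paths."""
    missing = [t for t in TASKS if t not in wav_paths]
    if missing:
        raise InputError(f"recording set incomplete, missing tasks: {missing}")
    transcriber = transcriber or SidecarTranscriber()
    wordlist = wordlist or WordList()

    features: dict[str, float] = {}
    for task in TASKS:
        raw = to_canonical(read_wav(wav_paths[task]))
        clean = denoise(raw)
        for name, value in prosodic_vector(clean).items():
            features[f"{task}__{name}"] = value
        transcript = transcriber.transcribe(clean, Path(wav_paths[task]))
        for name, value in lexical_vector(transcript, raw.duration_s, wordlist).items():
            features[f"{task}__{name}"] = value
    return {col: features[col] for col in FEATURE_COLUMNS}


def extract_from_manifest(
    manifest: pd.DataFrame,
    base_dir: Path,
    transcriber: Transcriber | None = None,
    wordlist: WordList | None = None,
) -> pd.DataFrame:
    """One feature row per subject listed in a cohort manifest.

    Subjects with an incomplete set of task recordings are skipped with a
    logged reason.
    """
    if len(manifest) == 0:
        raise InputError("manifest is empty")
    rows = []
    n_skipped = 0
    for subject, group in manifest.groupby("subject_id", sort=True):
        wav_paths = {
            str(r["task"]): base_dir / str(r["wav_path"]) for _, r in group.iterrows()
        }
        if set(wav_paths) != set(TASKS):
            n_skipped += 1
            logger.warning(
                "skipping %s: tasks present %s, need %s",
                subject, sorted(wav_paths), sorted(TASKS),
            )
            continue
        row = {"subject_id": subject}
        row.update(extract_assessment(wav_paths, transcriber, wordlist))
        rows.append(row)
    if n_skipped:
        logger.warning("%d incomplete recording sets excluded", n_skipped)
    if not rows:
        raise InputError("no complete recording sets in manifest")
    return pd.DataFrame(rows, columns=["subject_id", *FEATURE_COLUMNS])
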