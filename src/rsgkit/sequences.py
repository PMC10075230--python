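"""Data model and I/O for trial-level binary choice data.

The unit of analysis is a *block*: an ordered sequence of binary choices
(heads ``"H"`` / tails ``"T"``) together with per-trial success flags.
Trials on which a participant failed to respond in time are flagged
unsuccessful and are dropped before any sequence statistic is computed;
the remaining choices are concatenated (gaps are closed).

A participant contributes exactly five blocks plus quality metadata used
by the a-priori exclusion screen.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ALPHABET = ("H", "T")
CONDITIONS = ("ER", "FC", "IR", "MC", "PG")
N_BLOCKS = 5
NOMINAL_BLOCK_LENGTH = 200


class TrialFormatError(ValueError):
    """Raised when a trial file violates the expected schema."""


@dataclass
class ChoiceSequence:
    """One block of ordered binary choices with success flags.

    Parameters
    ----------
    symbols
        Ordered responses, each ``"H"`` or ``"T"``.
    success_flags
        Whether each trial was completed in time; failed trials are
        excluded from the effective sequence used downstream.
    block_index
        1-based position of the block within the session (1..5).
    nominal_length
        The intended number of trials per block (200 in the study design).
    """

    symbols: list[str]
    success_flags: list[bool]
    block_index: int
    nominal_length: int = NOMINAL_BLOCK_LENGTH

    def __post_init__(self) -> None:
        if len(self.symbols) != len(self.success_flags):
            raise ValueError(
                f"block {self.block_index}: {len(self.symbols)} symbols but "
                f"{len(self.success_flags)} success flags"
            )
        bad = set(self.symbols) - set(ALPHABET)
        if bad:
            raise ValueError(f"non-binary response tokens {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def n_failed(self) -> int:
        return sum(not f for f in self.success_flags)


@dataclass
class QualityMetadata:
    """Per-participant attention-check inputs for the exclusion screen."""

    instruction_reading_time_s: float = 120.0
    quiz_first_try_wrong: int = 0
    quiz_second_try_all_correct: bool = True
    post_task_probe_correct: bool = True
    max_consecutive_failed_per_block: tuple[int, ...] = (0, 0, 0, 0, 0)
    total_failed: int = 0
    browser_interactions_per_block: tuple[int, ...] = (0, 0, 0, 0, 0)
    pg_manipulation_detected: bool | None = None  # None = not applicable

    def __post_init__(self) -> None:
        if self.instruction_reading_time_s < 0:
            raise ValueError("reading time must be nonnegative")
        if self.total_failed < 0:
            raise ValueError("total_failed must be nonnegative")
        self.max_consecutive_failed_per_block = tuple(
            int(x) for x in self.max_consecutive_failed_per_block
        )
        self.browser_interactions_per_block = tuple(
            int(x) for x in self.browser_interactions_per_block
        )


@dataclass
class ParticipantRecord:
    """Five blocks of choices plus condition label and quality metadata."""

    participant_id: str
    condition: str
    blocks: list[ChoiceSequence]
    metadata: QualityMetadata = field(default_factory=QualityMetadata)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise TrialFormatError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        indices = [b.block_index for b in self.blocks]
        if sorted(indices) != indices:
            self.blocks = sorted(self.blocks, key=lambda b: b.block_index)


@dataclass
class StudyDataset:
    """A collection of participant records with provenance text."""

    records: list[ParticipantRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.participant_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate participant ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self, participant_id: str) -> ParticipantRecord:
        for r in self.records:
            if r.participant_id == participant_id:
                return r
        raise KeyError(participant_id)


def effective_sequence(block: ChoiceSequence) -> list[str]:
    """Return the symbols of successful trials, order preserved.

    Failed trials are omitted and the remaining choices concatenated, so
    downstream statistics see one contiguous sequence per block.
    """
    return [s for s, ok in zip(block.symbols, block.success_flags) if ok]


TRIAL_COLUMNS = ["participant_id", "condition", "block", "trial", "response", "success"]

_METADATA_COLUMNS = [
    "participant_id",
    "instruction_reading_time_s",
    "quiz_first_try_wrong",
    "quiz_second_try_all_correct",
    "post_task_probe_correct",
    "max_consecutive_failed_b1",
    "max_consecutive_failed_b2",
    "max_consecutive_failed_b3",
    "max_consecutive_failed_b4",
    "max_consecutive_failed_b5",
    "total_failed",
    "browser_interactions_b1",
    "browser_interactions_b2",
    "browser_interactions_b3",
    "browser_interactions_b4",
    "browser_interactions_b5",
    "pg_manipulation_detected",
]


def read_trials(path: str | Path, metadata_path: str | Path | None = None) -> StudyDataset:
    """Read a trial CSV (and optional metadata CSV) into a :class:`StudyDataset`.

    The trial file is comma-separated with a header and one row per trial:
    ``participant_id, condition, block, trial, response, success``.
    Responses must be ``H`` or ``T``; offending rows are reported by their
    1-based data row number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str, "condition": str, "response": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"{path}: missing required column(s) {missing}")

    bad = ~df["response"].isin(ALPHABET)
    if bad.any():
        row = int(df.index[bad][0]) + 1
        raise ValueError(
            f"{path}: non-binary response {df.loc[df.index[bad][0], 'response']!r} "
            f"at data row {row}"
        )
    bad_cond = ~df["condition"].isin(CONDITIONS)
    if bad_cond.any():
        label = df.loc[df.index[bad_cond][0], "condition"]
        raise TrialFormatError(f"{path}: unknown condition label {label!r}")

    metadata: dict[str, QualityMetadata] = {}
    if metadata_path is not None:
        metadata = _read_metadata(Path(metadata_path))

    records = []
    for pid, pdf in df.groupby("participant_id", sort=True):
        condition = pdf["condition"].iloc[0]
        blocks = []
        for bidx, bdf in pdf.groupby("block", sort=True):
            bdf = bdf.sort_values("trial")
            blocks.append(
                ChoiceSequence(
                    symbols=bdf["response"].tolist(),
                    success_flags=[bool(int(s)) for s in bdf["success"]],
                    block_index=int(bidx),
                )
            )
        records.append(
            ParticipantRecord(
                participant_id=str(pid),
                condition=condition,
                blocks=blocks,
                metadata=metadata.get(str(pid), QualityMetadata()),
            )
        )
    return StudyDataset(records=records, provenance=f"read_trials({path})")


def write_trials(
    dataset: StudyDataset,
    path: str | Path,
    metadata_path: str | Path | None = None,
) -> Path:
    """Write a dataset to a trial CSV; inverse of :func:`read_trials`.

    ``read_trials(write_trials(d)) == d`` field-for-field (provenance aside).
    """
    path = Path(path)
    rows = []
    for rec in dataset.records:
        for block in rec.blocks:
            for t, (sym, ok) in enumerate(zip(block.symbols, block.success_flags), start=1):
                rows.append(
                    (rec.participant_id, rec.condition, block.block_index, t, sym, int(ok))
                )
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)
    if metadata_path is not None:
        _write_metadata(dataset, Path(metadata_path))
    return path


def _read_metadata(path: Path) -> dict[str, QualityMetadata]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"{path}: missing metadata column(s) {missing}")
    out = {}
    for _, row in df.iterrows():
        pg = row["pg_manipulation_detected"]
        pg_val = None if pd.isna(pg) or str(pg) == "NA" else bool(int(pg))
        out[str(row["participant_id"])] = QualityMetadata(
            instruction_reading_time_s=float(row["instruction_reading_time_s"]),
            quiz_first_try_wrong=int(row["quiz_first_try_wrong"]),
            quiz_second_try_all_correct=bool(int(row["quiz_second_try_all_correct"])),
            post_task_probe_correct=bool(int(row["post_task_probe_correct"])),
            max_consecutive_failed_per_block=tuple(
                int(row[f"max_consecutive_failed_b{i}"]) for i in range(1, 6)
            ),
            total_failed=int(row["total_failed"]),
            browser_interactions_per_block=tuple(
                int(row[f"browser_interactions_b{i}"]) for i in range(1, 6)
            ),
            pg_manipulation_detected=pg_val,
        )
    return out


def _write_metadata(dataset: StudyDataset, path: Path) -> Path:
    rows = []
    for rec in dataset.records:
        m = rec.metadata
        row = {
            "participant_id": rec.participant_id,
            "instruction_reading_time_s": m.instruction_reading_time_s,
            "quiz_first_try_wrong": m.quiz_first_try_wrong,
            "quiz_second_try_all_correct": int(m.quiz_second_try_all_correct),
            "post_task_probe_correct": int(m.post_task_probe_correct),
            "total_failed": m.total_failed,
            "pg_manipulation_detected": (
                "NA" if m.pg_manipulation_detected is None else int(m.pg_manipulation_detected)
            ),
        }
        for i in range(1, 6):
            row[f"max_consecutive_failed_b{i}"] = m.max_consecutive_failed_per_block[i - 1]
            row[f"browser_interactions_b{i}"] = m.browser_interactions_per_block[i - 1]
        rows.append(row)
    pd.DataFrame(rows, columns=_METADATA_COLUMNS).to_csv(path, index=False)
    return path


def failure_summary(dataset: StudyDataset) -> pd.DataFrame:
    """Per-participant failed-trial counts and fractions.

    Returns a frame indexed by participant with columns ``n_failed``,
    ``n_trials`` and ``failed_fraction``; the dataset-level mean and SD of
    the counts are attached as ``frame.attrs['mean_failed']`` and
    ``frame.attrs['sd_failed']``.
    """
    rows = []
    for rec in dataset.records:
        n_failed = sum(b.n_failed for b in rec.blocks)
        n_trials = sum(len(b) for b in rec.blocks)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "n_failed": n_failed,
                "n_trials": n_trials,
                "failed_fraction": n_failed / n_trials if n_trials else 0.0,
            }
        )
    frame = pd.DataFrame(rows).set_index("participant_id")
    frame.attrs["mean_failed"] = float(frame["n_failed"].mean()) if len(frame) else 0.0
    frame.attrs["sd_failed"] = float(frame["n_failed"].std(ddof=1)) if len(frame) > 1 else 0.0
    return frame
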