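"""A-priori data-quality exclusions for online choice-sequence studies.

Participants are screened on attention-check metadata (instruction
reading time, comprehension quiz, post-task probe, failed-trial counts,
browser interactions) plus two behavioural removals: constant-button
blocks (a single option pressed throughout at least one block) and, in
the perceptual-guessing condition, detection of the manipulation.

Threshold inequalities are strict where the criteria are worded as
"less than" / "more than": e.g. exactly 15 consecutive failed trials is
acceptable, 16 is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .sequences import ParticipantRecord, StudyDataset, effective_sequence

# criterion labels, in screening order
READING_TIME = "reading_time"
QUIZ_FIRST_TRY = "quiz_first_try"
QUIZ_SECOND_TRY = "quiz_second_try"
POST_TASK_PROBE = "post_task_probe"
CONSECUTIVE_FAILED = "consecutive_failed"
TOTAL_FAILED = "total_failed"
BROWSER_INTERACTIONS = "browser_interactions"
CONSTANT_BUTTON = "constant_button"
PG_MANIPULATION = "pg_manipulation"

ALL_CRITERIA = (
    READING_TIME,
    QUIZ_FIRST_TRY,
    QUIZ_SECOND_TRY,
    POST_TASK_PROBE,
    CONSECUTIVE_FAILED,
    TOTAL_FAILED,
    BROWSER_INTERACTIONS,
    CONSTANT_BUTTON,
    PG_MANIPULATION,
)


@dataclass
class ExclusionCriteria:
    """Thresholds for the quality screen; defaults follow the study design.

    Bounds are exclusive where noted: a participant is rejected for
    *less than* ``min_reading_time_s`` seconds of reading, *more than*
    ``max_consecutive_failed`` successive failures in any block, *more
    than* ``max_total_failed`` failures overall, and *more than*
    ``max_browser_interactions_per_block`` interactions in any block.
    """

    min_reading_time_s: float = 60.0
    max_quiz_first_try_wrong: int = 2
    require_second_try_all_correct: bool = True
    require_post_task_probe: bool = True
    max_consecutive_failed: int = 15
    max_total_failed: int = 50
    max_browser_interactions_per_block: int = 3
    drop_constant_button_blocks: bool = True
    drop_pg_manipulation_detectors: bool = True

    def __post_init__(self) -> None:
        for name in (
            "min_reading_time_s",
            "max_quiz_first_try_wrong",
            "max_consecutive_failed",
            "max_total_failed",
            "max_browser_interactions_per_block",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class ExclusionReport:
    """Partition of a dataset into kept and rejected participants.

    ``attribution`` records how ``counts_per_criterion`` was tallied:
    ``"all"`` counts every criterion a participant fails (categories may
    overlap), ``"first"`` attributes each rejection to the first failed
    criterion in screening order (categories are disjoint).
    """

    kept: list[str]
    rejected: dict[str, list[str]]
    counts_per_criterion: dict[str, int]
    attribution: str = "all"


def constant_button_blocks(record: ParticipantRecord) -> list[int]:
    """Block indices whose effective sequence uses a single distinct symbol."""
    offending = []
    for block in record.blocks:
        seq = effective_sequence(block)
        if seq and len(set(seq)) == 1:
            offending.append(block.block_index)
    return offending


def _failed_criteria(record: ParticipantRecord, c: ExclusionCriteria) -> list[str]:
    m = record.metadata
    failed = []
    if m.instruction_reading_time_s < c.min_reading_time_s:
        failed.append(READING_TIME)
    if m.quiz_first_try_wrong > c.max_quiz_first_try_wrong:
        failed.append(QUIZ_FIRST_TRY)
    if c.require_second_try_all_correct and not m.quiz_second_try_all_correct:
        failed.append(QUIZ_SECOND_TRY)
    if c.require_post_task_probe and not m.post_task_probe_correct:
        failed.append(POST_TASK_PROBE)
    if max(m.max_consecutive_failed_per_block) > c.max_consecutive_failed:
        failed.append(CONSECUTIVE_FAILED)
    if m.total_failed > c.max_total_failed:
        failed.append(TOTAL_FAILED)
    if max(m.browser_interactions_per_block) > c.max_browser_interactions_per_block:
        failed.append(BROWSER_INTERACTIONS)
    if c.drop_constant_button_blocks and constant_button_blocks(record):
        failed.append(CONSTANT_BUTTON)
    if (
        c.drop_pg_manipulation_detectors
        and record.condition == "PG"
        and record.metadata.pg_manipulation_detected is True
    ):
        failed.append(PG_MANIPULATION)
    return failed


def apply_exclusions(
    dataset: StudyDataset,
    criteria: ExclusionCriteria | None = None,
    attribution: str = "all",
) -> ExclusionReport:
    """Screen every participant; reject those failing any enabled criterion.

    The report lists every failed criterion per rejected participant.
    ``attribution`` controls the per-criterion tallies only (see
    :class:`ExclusionReport`).
    """
    if attribution not in ("all", "first"):
        raise ValueError("attribution must be 'all' or 'first'")
    criteria = criteria or ExclusionCriteria()
    kept, rejected = [], {}
    counts = {label: 0 for label in ALL_CRITERIA}
    for rec in dataset.records:
        failed = _failed_criteria(rec, criteria)
        if failed:
            rejected[rec.participant_id] = failed
            tally = failed[:1] if attribution == "first" else failed
            for label in tally:
                counts[label] += 1
        else:
            kept.append(rec.participant_id)
    return ExclusionReport(
        kept=kept, rejected=rejected, counts_per_criterion=counts, attribution=attribution
    )


def kept_dataset(dataset: StudyDataset, report: ExclusionReport) -> StudyDataset:
    """Dataset restricted to the participants the report kept."""
    keep = set(report.kept)
    return StudyDataset(
        records=[r for r in dataset.records if r.participant_id in keep],
        provenance=dataset.provenance + " | exclusions applied",
    )
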