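import numpy as np
import pytest

from rsgkit.sequences import (
    ChoiceSequence,
    ParticipantRecord,
    QualityMetadata,
    StudyDataset,
)


def make_blocks(symbol_strings, success=None):
    """Build 5 blocks from strings like 'HTTH...'; success defaults to all-True."""
    blocks = []
    for i, s in enumerate(symbol_strings, start=1):
        flags = [True] * len(s) if success is None else list(success[i - 1])
        blocks.append(
            ChoiceSequence(
                symbols=list(s), success_flags=flags, block_index=i, nominal_length=len(s)
            )
        )
    return blocks


@pytest.fixture
def tiny_dataset():
    """Two participants, 5 short blocks each, clean metadata."""
    rng = np.random.default_rng(42)
    records = []
    for pid, cond in (("p1", "ER"), ("p2", "IR")):
        strings = [
            "".join(np.where(rng.integers(0, 2, 20) == 0, "H", "T")) for _ in range(5)
        ]
        records.append(
            ParticipantRecord(
                participant_id=pid,
                condition=cond,
                blocks=make_blocks(strings),
                metadata=QualityMetadata(),
            )
        )
    return StudyDataset(records=records, provenance="fixture")


@pytest.fixture
def fair_participant():
    """One participant with 5 blocks of 200 iid fair choices."""
    rng = np.random.default_rng(7)
    strings = [
        "".join(np.where(rng.integers(0, 2, 200) == 0, "H", "T")) for _ in range(5)
    ]
    return ParticipantRecord(
        participant_id="fair", condition="MC", blocks=make_blocks(strings)
    )
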