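"""Descriptive sequence statistics: balance, run lengths, cumulative traces.

Two simple properties characterise a binary choice sequence before any
model is fit:

* the **proportion value** ``max(n_H, n_T) / n`` — 0.5 for a perfectly
  balanced block, 1.0 when only one option was ever chosen;
* the **run lengths** — a run is a maximal streak of identical choices.
  The final run of a block is a truncated observation (the block ended,
  the run may not have), so it is omitted from run-length averages.

A seeded pseudorandom baseline (iid fair sequences pushed through the
same per-block rules) provides the comparison distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequences import StudyDataset, effective_sequence


def proportion_value(seq: Sequence[str]) -> float:
    """``max(n_H, n_T) / n``: 0.5 = balanced, 1.0 = single-option responding."""
    if len(seq) == 0:
        raise ValueError("proportion value is undefined for an empty sequence")
    n_h = sum(1 for s in seq if s == "H")
    return max(n_h, len(seq) - n_h) / len(seq)


def run_lengths(seq: Sequence[str], omit_last: bool = False) -> list[int]:
    """Lengths of maximal runs of identical choices, in order.

    With ``omit_last=True`` the final run is dropped, since the block ended
    while it was still ongoing (a truncated observation).
    """
    if len(seq) == 0:
        raise ValueError("run lengths are undefined for an empty sequence")
    runs = [len(list(g)) for _, g in groupby(seq)]
    return runs[:-1] if omit_last else runs


def mean_run_length(seq: Sequence[str], omit_last: bool = True) -> float:
    """Mean run length; NaN when omitting the last run leaves none."""
    runs = run_lengths(seq, omit_last=omit_last)
    return float(np.mean(runs)) if runs else float("nan")


def cumulative_trace(
    seq: Sequence[str], coding: Mapping[str, int] = {"H": -1, "T": 1}
) -> list[int]:
    """Running sum of ±1-coded choices (tails +1, heads −1 by default)."""
    return list(np.cumsum([coding[s] for s in seq]))


@dataclass
class BaselineSummary:
    """Distributional summary of a simulated fair-coin reference set."""

    n_sequences: int
    length: int
    mean_proportion: float
    sd_proportion: float
    mean_run_length: float
    sd_run_length: float


def pseudorandom_baseline(
    n_sequences: int = 78, length: int = 1000, seed: int = 0
) -> BaselineSummary:
    """Fair iid binary sequences processed with the per-block rules.

    Each sequence is split into 5 blocks of ``length/5``; per block the
    proportion value and mean run length (omit-last rule) are computed,
    averaged within sequence, then summarised (mean, SD) across sequences.
    """
    if n_sequences < 1:
        raise ValueError("need at least one sequence")
    if length % 5 != 0:
        raise ValueError("length must be divisible by 5 blocks")
    block_len = length // 5
    rng = np.random.default_rng(seed)
    props = np.empty(n_sequences)
    runs = np.empty(n_sequences)
    for i in range(n_sequences):
        digits = rng.integers(0, 2, size=length)
        seq = np.where(digits == 0, "H", "T")
        block_props = []
        block_runs = []
        for b in range(5):
            block = list(seq[b * block_len : (b + 1) * block_len])
            block_props.append(proportion_value(block))
            block_runs.append(mean_run_length(block, omit_last=True))
        props[i] = np.mean(block_props)
        runs[i] = np.nanmean(block_runs)
    return BaselineSummary(
        n_sequences=n_sequences,
        length=length,
        mean_proportion=float(props.mean()),
        sd_proportion=float(props.std(ddof=1)) if n_sequences > 1 else 0.0,
        mean_run_length=float(runs.mean()),
        sd_run_length=float(runs.std(ddof=1)) if n_sequences > 1 else 0.0,
    )


def descriptives_table(dataset: StudyDataset) -> pd.DataFrame:
    """Per-participant mean proportion value and mean run length.

    Block values are computed on effective (successful-trial) sequences and
    averaged over the five blocks, mirroring the block-mean convention used
    for the randomness outcomes. Blocks whose omit-last rule leaves no run
    contribute a missing value and are skipped in the participant mean.
    """
    rows = []
    for rec in dataset.records:
        props, runs = [], []
        for block in rec.blocks:
            seq = effective_sequence(block)
            if not seq:
                continue
            props.append(proportion_value(seq))
            runs.append(mean_run_length(seq, omit_last=True))
        rows.append(
            {
                "participant_id": rec.participant_id,
                "condition": rec.condition,
                "mean_proportion": float(np.mean(props)) if props else float("nan"),
                "mean_run_length": float(np.nanmean(runs)) if runs else float("nan"),
            }
        )
    return pd.DataFrame(rows)
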