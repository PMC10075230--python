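"""Markov-chain randomness measures for binary choice sequences.

A sequence of binary choices is modelled as a Markov chain of order *k*:
the distribution of the next choice depends on the preceding *k* choices.
Transition probabilities are estimated by maximum likelihood from the
``n − k`` subsequences of length ``k + 1``:

    p̂(s | c) = c(s, c) / Σ_s' c(s', c)

where ``c(s, c)`` counts how often context ``c`` (the previous *k*
choices) was followed by symbol ``s``.

Two outcome measures are derived per sequence:

* the **BIC-optimal order** — the order minimising
  ``BIC(k) = −2·logL(k) + 2^k·ln(n − k)``; this order estimator is
  statistically consistent, and quantifies the temporal extent of
  sequential dependencies;
* the **conditional entropy rate** at a fixed order (k = 3 by default) —
  the count-weighted average over contexts of the Shannon entropy of the
  next-choice distribution, in bits: 0 = perfectly determined,
  1 = perfectly random. The order is fixed rather than BIC-optimal so the
  estimate's small-sample bias is comparable across sequences; using an
  order above the true one does not change the quantity being estimated,
  because conditioning on additional irrelevant history does not reduce
  entropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sequences import ChoiceSequence, ParticipantRecord, effective_sequence

_SYM_TO_BIT = {"H": 0, "T": 1}
_BIT_TO_SYM = ("H", "T")


def _encode(seq: Sequence[str]) -> np.ndarray:
    try:
        return np.array([_SYM_TO_BIT[s] for s in seq], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"symbol {e.args[0]!r} not in alphabet ('H', 'T')") from None


def _context_codes(x: np.ndarray, k: int) -> np.ndarray:
    """Integer code of each length-k context window; predictions at offset k."""
    n = len(x)
    idx = np.zeros(n - k, dtype=np.int64)
    for j in range(k):
        idx = idx * 2 + x[j : n - k + j]
    return idx


def context_tuple(code: int, k: int) -> tuple[str, ...]:
    """Decode an integer context code into a tuple of symbols (oldest first)."""
    return tuple(_BIT_TO_SYM[(code >> (k - 1 - j)) & 1] for j in range(k))


@dataclass
class TransitionModel:
    """Order-k context → next-symbol count/probability table.

    ``count_table`` has shape ``(2**k, 2)``; row ``i`` is the context whose
    symbols spell the binary digits of ``i`` (H=0, T=1, oldest choice most
    significant), columns are the next symbol (H, T). Counts may be real
    (e.g. for exactly specified models); probabilities are the per-row
    normalisation. Rows with zero total count are unobserved contexts and
    carry no probability mass.
    """

    order_k: int
    count_table: np.ndarray

    def __post_init__(self) -> None:
        self.count_table = np.asarray(self.count_table, dtype=float)
        if self.count_table.shape != (2**self.order_k, 2):
            raise ValueError(
                f"count table for order {self.order_k} must have shape "
                f"{(2**self.order_k, 2)}, got {self.count_table.shape}"
            )
        if (self.count_table < 0).any():
            raise ValueError("counts must be nonnegative")

    @classmethod
    def fit(cls, seq: Sequence[str], k: int) -> "TransitionModel":
        """Maximum-likelihood fit from the ``len(seq) − k`` (k+1)-subsequences."""
        if k < 0:
            raise ValueError("order must be nonnegative")
        x = _encode(seq)
        if len(x) < k + 1:
            raise ValueError(
                f"cannot estimate order {k} from {len(x)} symbols; "
                f"need at least {k + 1}"
            )
        idx = _context_codes(x, k)
        nxt = x[k:]
        table = np.bincount(idx * 2 + nxt, minlength=2 ** (k + 1)).reshape(2**k, 2)
        return cls(order_k=k, count_table=table.astype(float))

    @classmethod
    def from_probabilities(
        cls,
        probabilities: np.ndarray,
        context_weights: np.ndarray | None = None,
    ) -> "TransitionModel":
        """Exactly specified model (no estimation).

        ``probabilities`` has shape ``(2**k, 2)`` with rows summing to 1;
        ``context_weights`` (default uniform) gives the stationary weight of
        each context. Stored as real-valued counts ``w_c · p(s|c)``.
        """
        probabilities = np.asarray(probabilities, dtype=float)
        n_ctx = probabilities.shape[0]
        k = int(np.log2(n_ctx))
        if 2**k != n_ctx or probabilities.shape != (n_ctx, 2):
            raise ValueError("probabilities must have shape (2**k, 2)")
        if not np.allclose(probabilities.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each context's probabilities must sum to 1")
        if context_weights is None:
            context_weights = np.full(n_ctx, 1.0 / n_ctx)
        context_weights = np.asarray(context_weights, dtype=float)
        return cls(order_k=k, count_table=probabilities * context_weights[:, None])

    @classmethod
    def fair_coin(cls, k: int) -> "TransitionModel":
        """The exact model in which every next choice is uniform (0.5, 0.5)."""
        return cls.from_probabilities(np.full((2**k, 2), 0.5))

    # -- derived views ----------------------------------------------------

    @property
    def context_totals(self) -> np.ndarray:
        return self.count_table.sum(axis=1)

    @property
    def total_transitions(self) -> float:
        return float(self.count_table.sum())

    @property
    def probability_table(self) -> np.ndarray:
        """Per-row normalised probabilities; NaN rows for unobserved contexts."""
        totals = self.context_totals
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals[:, None] > 0, self.count_table / totals[:, None], np.nan)

    @property
    def contexts(self) -> list[tuple[str, ...]]:
        """Observed contexts, as symbol tuples (oldest choice first)."""
        totals = self.context_totals
        return [context_tuple(i, self.order_k) for i in np.flatnonzero(totals > 0)]

    def _ctx_code(self, context: Sequence[str]) -> int:
        if len(context) != self.order_k:
            raise ValueError(f"context must have length {self.order_k}")
        code = 0
        for s in context:
            code = code * 2 + _SYM_TO_BIT[s]
        return code

    def count(self, context: Sequence[str], symbol: str) -> float:
        return float(self.count_table[self._ctx_code(context), _SYM_TO_BIT[symbol]])

    def probability(self, context: Sequence[str], symbol: str) -> float:
        return float(self.probability_table[self._ctx_code(context), _SYM_TO_BIT[symbol]])


def log_likelihood(model: TransitionModel, seq: Sequence[str] | None = None) -> float:
    """Log-likelihood (natural log) of a sequence under the model.

    With ``seq=None`` the self-fit likelihood is returned from the model's
    own counts, ``Σ c·ln(p̂)`` with ``0·ln 0 := 0``. With a foreign
    sequence, positions are scored one by one; a position whose context or
    symbol has probability zero yields ``-inf`` (flagged with a warning).
    """
    if seq is None:
        counts = model.count_table
        probs = model.probability_table
        mask = counts > 0
        return float(np.sum(counts[mask] * np.log(probs[mask])))
    x = _encode(seq)
    k = model.order_k
    if len(x) < k + 1:
        raise ValueError(f"sequence shorter than order {k} + 1")
    idx = _context_codes(x, k)
    nxt = x[k:]
    p = model.probability_table[idx, nxt]
    if np.any(~(p > 0)):  # catches 0 and NaN (unobserved context)
        warnings.warn("sequence contains transitions with zero probability under model")
        return float("-inf")
    return float(np.log(p).sum())


def _self_fit_log_likelihood(x: np.ndarray, k: int, start: int | None = None) -> float:
    """Self-fit logL at order k, optionally restricted to positions >= start.

    Restricting all orders to a common prediction set (start = k_max) makes
    the self-fit likelihood non-decreasing in k (nested models); the
    default per-order set predicts all n − k positions.
    """
    if start is None:
        start = k
    if start < k:
        raise ValueError("start must be at least k")
    idx = _context_codes(x, k)[start - k :]
    nxt = x[start:]
    counts = np.bincount(idx * 2 + nxt, minlength=2 ** (k + 1)).reshape(2**k, 2)
    totals = counts.sum(axis=1)
    mask = counts > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / totals[:, None]
    return float(np.sum(counts[mask] * np.log(probs[mask])))


@dataclass
class OrderSelection:
    """BIC values over candidate orders 0..k_max and the selected minimum."""

    candidate_orders: list[int]
    log_likelihoods: list[float]
    n_params: list[int]
    bic_values: list[float]
    selected_order: int


def bic(log_lik: float, k: int, n_predictions: int) -> float:
    """``−2·logL + 2^k·ln(N_k)`` with ``N_k`` the number of predicted positions."""
    return -2.0 * log_lik + (2**k) * np.log(n_predictions)


def select_order(
    seq: Sequence[str], k_max: int = 5, common_prediction_set: bool = False
) -> OrderSelection:
    """Choose the Markov order minimising BIC; ties go to the smaller order.

    Each candidate order k is fit by maximum likelihood on its own
    ``n − k`` predicted positions (the default), or on the common position
    set ``k_max..n−1`` when ``common_prediction_set`` is set.
    """
    x = _encode(seq)
    if k_max >= len(x):
        raise ValueError(f"k_max={k_max} too large for sequence of length {len(x)}")
    if k_max < 0:
        raise ValueError("k_max must be nonnegative")
    orders = list(range(k_max + 1))
    lls, bics = [], []
    for k in orders:
        start = k_max if common_prediction_set else k
        ll = _self_fit_log_likelihood(x, k, start=start)
        n_pred = len(x) - start
        lls.append(ll)
        bics.append(bic(ll, k, n_pred))
    best = int(np.argmin(bics))  # argmin returns the first (smallest) order on ties
    return OrderSelection(
        candidate_orders=orders,
        log_likelihoods=lls,
        n_params=[2**k for k in orders],
        bic_values=bics,
        selected_order=orders[best],
    )


def conditional_entropy_rate(model: TransitionModel) -> float:
    """Count-weighted conditional entropy of the next choice, in bits.

    ``Σ_c w(c) · H₂(p̂(·|c))`` with ``w(c)`` the context's share of all
    transitions and ``H₂`` the binary Shannon entropy (``0·log 0 := 0``).
    Ranges from 0 (every observed context deterministic) to 1 bit
    (uniform next-choice distribution everywhere).
    """
    totals = model.context_totals
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("model has no observed transitions")
    weights = totals / grand
    probs = model.probability_table
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    row_entropy = np.where(totals > 0, -np.nansum(plogp, axis=1), 0.0)
    return float(np.dot(weights, row_entropy))


@dataclass
class RandomnessScores:
    """Per-block and mean outcomes for one participant.

    Blocks too short to score at the fixed order contribute NaN and are
    dropped from the means.
    """

    participant_id: str
    condition: str
    per_block_entropy_bits: list[float]
    per_block_optimal_order: list[float]
    mean_entropy_bits: float
    mean_optimal_order: float


def score_sequence(
    seq: Sequence[str], fixed_k: int = 3, k_max: int = 5
) -> tuple[float, int]:
    """(conditional entropy at ``fixed_k`` in bits, BIC-optimal order)."""
    model = TransitionModel.fit(seq, fixed_k)
    entropy = conditional_entropy_rate(model)
    order = select_order(seq, k_max=k_max).selected_order
    return entropy, order


def score_participant(
    record: ParticipantRecord, fixed_k: int = 3, k_max: int = 5
) -> RandomnessScores:
    """Score each block on its effective sequence; outcomes are block means."""
    entropies, orders = [], []
    for block in record.blocks:
        seq = effective_sequence(block)
        if len(seq) < max(fixed_k, k_max) + 1:
            warnings.warn(
                f"participant {record.participant_id} block {block.block_index}: "
                f"only {len(seq)} successful trials; block scores set to missing"
            )
            entropies.append(float("nan"))
            orders.append(float("nan"))
            continue
        entropy, order = score_sequence(seq, fixed_k=fixed_k, k_max=k_max)
        entropies.append(entropy)
        orders.append(float(order))
    return RandomnessScores(
        participant_id=record.participant_id,
        condition=record.condition,
        per_block_entropy_bits=entropies,
        per_block_optimal_order=orders,
        mean_entropy_bits=float(np.nanmean(entropies)),
        mean_optimal_order=float(np.nanmean(orders)),
    )


def score_dataset(dataset, fixed_k: int = 3, k_max: int = 5):
    """Score every participant; returns (per-block frame, participant frame)."""
    import pandas as pd

    block_rows, part_rows = [], []
    for rec in dataset.records:
        scores = score_participant(rec, fixed_k=fixed_k, k_max=k_max)
        for i, (e, o) in enumerate(
            zip(scores.per_block_entropy_bits, scores.per_block_optimal_order), start=1
        ):
            block_rows.append(
                {
                    "participant_id": rec.participant_id,
                    "condition": rec.condition,
                    "block": i,
                    "entropy_bits": e,
                    "optimal_order": o,
                }
            )
        part_rows.append(
            {
                "participant_id": rec.participant_id,
                "condition": rec.condition,
                "mean_entropy_bits": scores.mean_entropy_bits,
                "mean_optimal_order": scores.mean_optimal_order,
            }
        )
    return pd.DataFrame(block_rows), pd.DataFrame(part_rows)
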