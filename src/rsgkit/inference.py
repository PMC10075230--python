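"""Between-condition inference for per-participant randomness outcomes.

The outcomes (mean conditional entropy, mean optimal Markov order) are
bounded and non-normal, so the omnibus comparison across instruction
conditions is a tie-corrected Kruskal–Wallis test. Its effect size is the
rank-based eta-squared

    η²_H = (H − g + 1) / (N − g),

convertible to Cohen's f = sqrt(η²/(1−η²)) and d = 2f. Pairwise
follow-ups compare group mean ranks with a Tukey–Kramer (studentized
range) adjustment honouring unequal group sizes. A two-stage block
analysis (per-participant regression on block number, then one-way ANOVA
of the intercepts) checks that block-order effects such as fatigue do
not drive the condition differences. A noncentral-F power calculator
reproduces the a-priori ANOVA sample-size estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


# --------------------------------------------------------------------------
# Kruskal–Wallis and effect sizes
# --------------------------------------------------------------------------

def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and chi-squared p-value (df = g − 1).

    By convention a completely constant pooled sample gives H = 0, p = 1
    (no evidence of any group difference).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group needs at least one observation")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def kw_eta_squared(h: float, n_total: int, n_groups: int) -> float:
    """Rank-based eta-squared ``(H − g + 1)/(N − g)``, clipped below at 0."""
    if n_total <= n_groups:
        raise ValueError("n_total must exceed n_groups")
    return max(0.0, (h - n_groups + 1) / (n_total - n_groups))


def eta2_to_cohens_d(eta_squared: float) -> float:
    """Cohen's d via f = sqrt(η²/(1−η²)), d = 2f."""
    if not 0.0 <= eta_squared < 1.0:
        raise ValueError("eta squared must lie in [0, 1)")
    return 2.0 * np.sqrt(eta_squared / (1.0 - eta_squared))


def cohens_d_to_eta2(d: float) -> float:
    """Inverse of :func:`eta2_to_cohens_d` (f² / (1 + f²) with f = d/2)."""
    f2 = (d / 2.0) ** 2
    return f2 / (1.0 + f2)


def eta_squared_ci(
    groups: list[np.ndarray],
    n_boot: int = 1000,
    confidence: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile-bootstrap CI for the Kruskal–Wallis eta-squared.

    Participants are resampled with replacement within each group.
    """
    rng = np.random.default_rng(seed)
    groups = [np.asarray(g, dtype=float) for g in groups]
    g = len(groups)
    n_total = sum(len(x) for x in groups)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        resampled = [rng.choice(x, size=len(x), replace=True) for x in groups]
        h, _ = kruskal_wallis(resampled)
        boot[b] = kw_eta_squared(h, n_total, g)
    lo = (1.0 - confidence) / 2.0
    return (
        float(np.quantile(boot, lo)),
        float(np.quantile(boot, 1.0 - lo)),
    )


# --------------------------------------------------------------------------
# Tukey–Kramer post-hoc on mean ranks
# --------------------------------------------------------------------------

def tukey_kramer_ranks(groups: list[np.ndarray], alpha: float = 0.05) -> np.ndarray:
    """Pairwise adjusted p-values for group mean-rank differences.

    Follows the large-sample rank comparison used after a Kruskal–Wallis
    test: pooled midranks, tie-corrected rank variance N(N+1)/12, and the
    studentized-range distribution with infinite error degrees of freedom.
    The Tukey–Kramer form ``SE_ij² = S²·(1/n_i + 1/n_j)`` accommodates
    unequal group sizes. Returns a symmetric (g × g) matrix with 1 on the
    diagonal.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(x) == 0 for x in groups):
        raise ValueError("every group needs at least one observation")
    sizes = np.array([len(x) for x in groups])
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction to the null rank variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_adj = np.sum(tie_counts**3 - tie_counts) / (n**3 - n) if n > 1 else 0.0
    s2 = n * (n + 1) / 12.0 * (1.0 - tie_adj)
    mean_ranks = []
    offset = 0
    for size in sizes:
        mean_ranks.append(ranks[offset : offset + size].mean())
        offset += size
    mean_ranks = np.array(mean_ranks)
    g = len(groups)
    pmat = np.ones((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            se = np.sqrt(s2 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if se == 0:
                p = 1.0
            else:
                q = abs(mean_ranks[i] - mean_ranks[j]) / se * np.sqrt(2.0)
                p = float(stats.studentized_range.sf(q, g, np.inf))
            pmat[i, j] = pmat[j, i] = min(1.0, p)
    return pmat


@dataclass
class GroupComparison:
    """Omnibus + effect-size + post-hoc summary for one outcome variable."""

    group_labels: list[str]
    group_sizes: list[int]
    H: float
    p_value: float
    eta_squared: float
    eta_squared_ci: tuple[float, float]
    cohens_d: float
    pairwise_p: np.ndarray  # Tukey–Kramer adjusted, symmetric, unit diagonal


def compare_groups(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> GroupComparison:
    """Full between-condition comparison of one outcome.

    Runs the Kruskal–Wallis test, computes rank-based eta-squared with a
    seeded percentile-bootstrap CI, converts to Cohen's d, and produces the
    Tukey–Kramer adjusted pairwise p matrix on mean ranks.
    """
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    samples = [s[~np.isnan(s)] for s in samples]
    h, p = kruskal_wallis(samples)
    n_total = sum(len(s) for s in samples)
    eta2 = kw_eta_squared(h, n_total, len(samples))
    ci = eta_squared_ci(samples, n_boot=n_boot, seed=seed)
    return GroupComparison(
        group_labels=labels,
        group_sizes=[len(s) for s in samples],
        H=h,
        p_value=p,
        eta_squared=eta2,
        eta_squared_ci=ci,
        cohens_d=eta2_to_cohens_d(eta2),
        pairwise_p=tukey_kramer_ranks(samples, alpha=alpha),
    )


# --------------------------------------------------------------------------
# Two-stage block ("multilevel") analysis
# --------------------------------------------------------------------------

@dataclass
class BlockEffectResult:
    """Stage-1 per-participant fits and stage-2 ANOVA across conditions."""

    per_participant_intercepts: dict[str, float]
    per_participant_slopes: dict[str, float]
    slope_mean: float
    slope_sd: float
    anova_F: float
    anova_p: float


def block_effect_analysis(
    block_scores: dict[str, list[float]],
    conditions: dict[str, str],
    center_block: float = 3.0,
) -> BlockEffectResult:
    """Two-stage analysis of block-order effects on an outcome.

    Stage 1 regresses each participant's outcome on the block number
    centred at mid-experiment (block 3), so the intercept estimates the
    participant's mid-experiment level net of any linear drift (e.g.
    fatigue). Stage 2 submits the intercepts to a one-way ANOVA across
    conditions. Participants with fewer than two non-missing block values
    are skipped.
    """
    intercepts, slopes = {}, {}
    for pid, values in block_scores.items():
        values = np.asarray(values, dtype=float)
        blocks = np.arange(1, len(values) + 1, dtype=float)
        ok = ~np.isnan(values)
        if ok.sum() < 2:
            import warnings

            warnings.warn(f"participant {pid}: fewer than 2 block values; skipped")
            continue
        slope, intercept = np.polyfit(blocks[ok] - center_block, values[ok], 1)
        intercepts[pid] = float(intercept)
        slopes[pid] = float(slope)
    by_condition: dict[str, list[float]] = {}
    for pid, b0 in intercepts.items():
        by_condition.setdefault(conditions[pid], []).append(b0)
    samples = [np.array(v) for v in by_condition.values()]
    if len(samples) >= 2 and all(len(s) >= 2 for s in samples):
        if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(*samples)
    else:
        f_stat, p = float("nan"), float("nan")
    slope_values = np.array(list(slopes.values()))
    return BlockEffectResult(
        per_participant_intercepts=intercepts,
        per_participant_slopes=slopes,
        slope_mean=float(slope_values.mean()) if len(slope_values) else float("nan"),
        slope_sd=float(slope_values.std(ddof=1)) if len(slope_values) > 1 else float("nan"),
        anova_F=float(f_stat),
        anova_p=float(p),
    )


# --------------------------------------------------------------------------
# A-priori power analysis
# --------------------------------------------------------------------------

@dataclass
class PowerSpec:
    """One-way ANOVA power-analysis inputs and the resulting total N."""

    effect_size_f: float
    alpha: float
    power: float
    n_groups: int
    required_total_n: int | None = None


def anova_power(total_n: int, effect_size_f: float, n_groups: int, alpha: float) -> float:
    """Power of a balanced one-way ANOVA via the noncentral F distribution.

    ``P(F′(g−1, N−g, λ = f²·N) > F_crit(g−1, N−g, α))``.
    """
    df1 = n_groups - 1
    df2 = total_n - n_groups
    if df2 < 1:
        return 0.0
    lam = effect_size_f**2 * total_n
    f_crit = stats.f.isf(alpha, df1, df2)
    return float(stats.ncf.sf(f_crit, df1, df2, lam))


def anova_sample_size(spec: PowerSpec, max_total_n: int = 100_000) -> PowerSpec:
    """Smallest balanced total N reaching the target power.

    Scans balanced sizes (multiples of ``n_groups``) upward; raises if the
    target power is unreachable below ``max_total_n``.
    """
    if not (0.0 < spec.alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if not (0.0 < spec.power < 1.0):
        raise ValueError("target power must be in (0, 1)")
    if spec.effect_size_f <= 0:
        raise ValueError("effect size f must be positive")
    if spec.n_groups < 2:
        raise ValueError("need at least two groups")
    g = spec.n_groups
    n = max(2 * g, g + 2)
    n += (-n) % g  # round up to a balanced size
    while n <= max_total_n:
        if anova_power(n, spec.effect_size_f, g, spec.alpha) >= spec.power:
            return PowerSpec(
                effect_size_f=spec.effect_size_f,
                alpha=spec.alpha,
                power=spec.power,
                n_groups=g,
                required_total_n=n,
            )
        n += g
    raise ValueError(f"target power not reachable below N = {max_total_n}")
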