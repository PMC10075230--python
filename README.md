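# rsgkit

Markov-chain randomness analysis of human binary choice sequences.

## The problem

In a random-sequence-generation (RSG) task, people produce a long series of
binary choices — think repeated calls of *heads* or *tails* — while trying to
be unpredictable. Humans are famously bad at this: they alternate too often,
balance the options too carefully, and fall into short-range patterns. How
random a produced sequence actually is, and how the instruction wording
("be random", "be irregular", "imagine a coin toss", free choice, perceptual
guessing) changes it, is a question for experimental psychology with methods
straight from stochastic-process theory.

`rsgkit` packages that analysis pipeline for researchers running such
studies: data model and CSV I/O for trial-level choice data, a-priori
data-quality exclusions, descriptive sequence statistics, Markov-chain
randomness scores, nonparametric between-condition inference, an ANOVA power
calculator, and a synthetic-study generator so the whole pipeline runs and is
testable without any real data.

## The model

A choice sequence X₁, X₂, … over {H, T} is modelled as a Markov chain of
order *k*: the next choice depends on the previous *k* choices through
transition probabilities Pr(Xₜ | Xₜ₋₁, …, Xₜ₋ₖ), estimated by maximum
likelihood from the n − k subsequences of length k + 1,

    p̂(s | c) = c(s, c) / Σ_s' c(s', c).

Two outcome measures are computed per 200-choice block and averaged over a
participant's five blocks:

* **Optimal Markov order** — the k ∈ {0, …, k_max} minimising
  BIC(k) = −2·log L(k) + 2ᵏ·ln(n − k); this order estimator is statistically
  consistent. It measures the temporal extent of sequential dependence
  (order 0 = sequentially independent).
* **Conditional entropy rate** at fixed k = 3 —
  Σ_c w(c)·H₂(p̂(·|c)) in bits, with w(c) the context's share of transitions:
  0 bits = perfectly determined, 1 bit = perfectly random. The order is fixed
  so that the plug-in estimator's small-sample bias is comparable across
  participants; conditioning on extra irrelevant history does not change the
  estimated quantity.

Between-condition inference uses a tie-corrected Kruskal–Wallis test with the
rank-based effect size η²_H = (H − g + 1)/(N − g), converted to Cohen's
f = √(η²/(1−η²)) and d = 2f, plus Tukey–Kramer-adjusted pairwise
comparisons of group mean ranks.

## Worked example

```python
import rsgkit as rk

dataset = rk.gen_study({c: 40 for c in ("ER", "FC", "IR", "MC", "PG")}, seed=11)
report = rk.apply_exclusions(dataset)
kept = rk.kept_dataset(dataset, report)
print(f"kept {len(report.kept)} of {len(dataset)} participants")

blocks, participants = rk.score_dataset(kept, fixed_k=3, k_max=5)
print(participants.groupby("condition")[["mean_entropy_bits", "mean_optimal_order"]]
      .median().round(2))

groups = {c: sub["mean_entropy_bits"].to_numpy()
          for c, sub in participants.groupby("condition")}
comp = rk.compare_groups(groups, n_boot=500, seed=11)
print(f"H = {comp.H:.1f}, p = {comp.p_value:.2e}")
print(f"eta2 = {comp.eta_squared:.2f} "
      f"(95% CI {comp.eta_squared_ci[0]:.2f}-{comp.eta_squared_ci[1]:.2f}), "
      f"d = {comp.cohens_d:.2f}")
```

prints

```
kept 135 of 200 participants
           mean_entropy_bits  mean_optimal_order
condition
ER                      0.86                 1.0
FC                      0.74                 1.0
IR                      0.90                 1.0
MC                      0.96                 0.4
PG                      0.85                 1.0
H = 46.1, p = 2.32e-09
eta2 = 0.32 (95% CI 0.22-0.47), d = 1.38
```

Reading this: 65 simulated participants were screened out by the attention
and data-quality criteria (including the deliberately common manipulation
detection in the PG condition). Of the kept participants, the
mental-coin-toss and irregularity groups produce the most random sequences
(median entropy 0.96 and 0.90 bits), free choice the least (0.74 bits), and
the omnibus Kruskal–Wallis test rejects equality of conditions decisively
with a large rank-based effect size. The condition presets of the generator
are built to reproduce exactly this qualitative ordering.

The same pipeline is available from the shell:

```bash
rsgkit simulate --n 40 --seed 11 --out sim/
rsgkit exclude sim/trials.csv --metadata sim/metadata.csv --out excl.json
rsgkit score sim/trials.csv --out scores
rsgkit compare scores_participants.csv --out comparison.json
rsgkit run --seed 11 --out results/   # all of the above in one step
```

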