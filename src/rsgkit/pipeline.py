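"""End-to-end pipeline: simulate/load → exclude → score → compare.

Every stage consumes and produces the package's CSV/JSON interfaces, so
stages can be run individually (see :mod:`rsgkit.cli`) or composed here.
All randomness is routed through a single master seed recorded in the
provenance manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .descriptives import descriptives_table
from .exclusion import ExclusionCriteria, apply_exclusions, kept_dataset
from .inference import compare_groups
from .markov import score_dataset
from .sequences import StudyDataset, read_trials, write_trials
from .simulate import MetadataSpec, gen_study


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run; defaults match the study design."""

    input_trials: str | None = None  # CSV path; None → simulate
    input_metadata: str | None = None
    n_per_condition: dict[str, int] = field(
        default_factory=lambda: {c: 78 for c in ("ER", "FC", "IR", "MC", "PG")}
    )
    exclusion: ExclusionCriteria = field(default_factory=ExclusionCriteria)
    fixed_k: int = 3
    k_max: int = 5
    alpha: float = 0.05
    bootstrap_reps: int = 1000
    seed: int = 0
    out_dir: str = "rsgkit_out"

    def __post_init__(self) -> None:
        if self.fixed_k < 0:
            raise ValueError("fixed_k must be nonnegative")


def _comparison_to_dict(comp) -> dict:
    return {
        "group_labels": comp.group_labels,
        "group_sizes": comp.group_sizes,
        "H": comp.H,
        "p_value": comp.p_value,
        "eta_squared": comp.eta_squared,
        "eta_squared_ci": list(comp.eta_squared_ci),
        "cohens_d": comp.cohens_d,
        "pairwise_p": np.asarray(comp.pairwise_p).tolist(),
    }


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full analysis and write its report bundle.

    Writes, under ``config.out_dir``: the (simulated) trial and metadata
    CSVs, the exclusion report, per-block and per-participant scores,
    descriptives, one group-comparison JSON per outcome, and a manifest
    with config hash, seed and package version. Partial outputs are
    removed if any stage fails.
    """
    out = Path(config.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run(config, out)
    except Exception:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise


def _run(config: PipelineConfig, out: Path) -> dict[str, Path]:
    paths: dict[str, Path] = {}

    if config.input_trials is not None:
        dataset = read_trials(config.input_trials, config.input_metadata)
    else:
        dataset = gen_study(config.n_per_condition, seed=config.seed)
        paths["trials"] = write_trials(
            dataset, out / "trials.csv", out / "metadata.csv"
        )
        paths["metadata"] = out / "metadata.csv"

    report = apply_exclusions(dataset, config.exclusion)
    paths["exclusions"] = out / "exclusion_report.json"
    paths["exclusions"].write_text(
        json.dumps(
            {
                "kept": report.kept,
                "rejected": report.rejected,
                "counts_per_criterion": report.counts_per_criterion,
                "attribution": report.attribution,
            },
            indent=2,
        )
    )
    kept = kept_dataset(dataset, report)

    conditions_present = {r.condition for r in kept.records}
    missing = set(config.n_per_condition) - conditions_present if config.input_trials is None else set()
    if config.input_trials is None and missing:
        raise RuntimeError(
            f"no participants left after exclusion in condition(s): {sorted(missing)}"
        )
    if not kept.records:
        raise RuntimeError("no participants left after exclusion")

    block_scores, participant_scores = score_dataset(
        kept, fixed_k=config.fixed_k, k_max=config.k_max
    )
    paths["scores_blocks"] = out / "scores_blocks.csv"
    block_scores.to_csv(paths["scores_blocks"], index=False)
    paths["scores_participants"] = out / "scores_participants.csv"
    participant_scores.to_csv(paths["scores_participants"], index=False)

    paths["descriptives"] = out / "descriptives.csv"
    descriptives_table(kept).to_csv(paths["descriptives"], index=False)

    for outcome, col in (
        ("entropy", "mean_entropy_bits"),
        ("order", "mean_optimal_order"),
    ):
        groups = {
            cond: sub[col].to_numpy()
            for cond, sub in participant_scores.groupby("condition")
        }
        comp = compare_groups(
            groups,
            alpha=config.alpha,
            n_boot=config.bootstrap_reps,
            seed=config.seed,
        )
        p = out / f"comparison_{outcome}.json"
        p.write_text(json.dumps(_comparison_to_dict(comp), indent=2))
        paths[f"comparison_{outcome}"] = p

    config_dict = dataclasses.asdict(config)
    manifest = {
        "rsgkit_version": __version__,
        "seed": config.seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=str))
    return paths
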