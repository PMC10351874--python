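"""Pipeline driver: simulate/load -> extract -> train -> evaluate -> rank -> select.

A run evaluates exactly one cohort: either all 31 feature combinations at a
fixed muscle set (default MG+BF+GMax), or all 255 muscle combinations at a
fixed feature set (default IEMG+WL).  Every stochastic stage draws its seed
deterministically from the master seed and logs it, so a run is fully
reconstructible from (config, master_seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .combinations import FeatureSet, MuscleSet, all_feature_sets, all_muscle_sets
from .errors import EmptySelectionError, ValidationError
from .features import WindowSpec
from .io import read_dataset
from .predictor import ModelSpec, make_split
from .ranking import (
    RankingTable,
    VariationSelection,
    evaluate_combination,
    finalize_scores,
    rank_variations,
    select_variations,
)
from .synthetic_gait import SynthConfig, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("myoankle")


@dataclass
class PipelineConfig:
    """Full configuration of one ranking run."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    window: WindowSpec = field(default_factory=WindowSpec)
    pos_model: ModelSpec = field(default_factory=lambda: ModelSpec(target="position"))
    mom_model: ModelSpec = field(default_factory=lambda: ModelSpec(target="moment"))
    cohort: str = "feature_selection"
    fixed_muscles: str = "MG+BF+GMax"
    fixed_features: str = "IEMG+WL"
    n_trials: int = 20
    data_dir: str | None = None
    split_fraction: float = 0.80
    alpha: float = 0.05
    r_threshold: float = 0.90
    spm_method: str = "permutation"
    n_permutations: int = 1000
    output_dir: str = "myoankle_out"
    master_seed: int = 0

    def __post_init__(self):
        if self.cohort not in ("feature_selection", "muscle_selection"):
            raise ValidationError("cohort must be feature_selection or muscle_selection")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "synth" in kwargs:
            kwargs["synth"] = SynthConfig(**kwargs["synth"])
        if "window" in kwargs:
            kwargs["window"] = WindowSpec(**kwargs["window"])
        if "pos_model" in kwargs:
            kwargs["pos_model"] = ModelSpec(**{"target": "position", **kwargs["pos_model"]})
        if "mom_model" in kwargs:
            kwargs["mom_model"] = ModelSpec(**{"target": "moment", **kwargs["mom_model"]})
        return cls(**kwargs)


def run_pipeline(
    config: PipelineConfig,
) -> tuple[RankingTable, VariationSelection | None, dict[str, Path]]:
    """Execute one full cohort run and write all artifacts under output_dir.

    Returns the ranking table, the variation selection (muscle cohorts only;
    None when no combination passes the eligibility filters, in which case
    the audit is still written), and the artifact paths.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def note(msg: str) -> None:
        log.info(msg)
        log_lines.append(msg)

    seed_rng = np.random.default_rng(config.master_seed)
    data_seed = int(seed_rng.integers(2**31 - 1))
    split_seed = int(seed_rng.integers(2**31 - 1))

    if config.data_dir:
        trials = read_dataset(config.data_dir)
        note(f"loaded {len(trials)} trials from {config.data_dir}")
    else:
        trials = generate_dataset(config.synth, config.n_trials, seed=data_seed)
        note(f"simulated {len(trials)} trials (data_seed={data_seed})")

    split = make_split(trials, fraction=config.split_fraction, seed=split_seed)
    note(
        f"split seed={split_seed}: {len(split.train_ids)} train / {len(split.valid_ids)} valid"
    )

    if config.cohort == "feature_selection":
        ms_fixed = MuscleSet.parse(config.fixed_muscles)
        combos = [(ms_fixed, fs, fs.name) for fs in all_feature_sets()]
        note(f"feature cohort: {len(combos)} combinations at muscles {ms_fixed.name}")
    else:
        fs_fixed = FeatureSet.parse(config.fixed_features)
        combos = [(ms, fs_fixed, ms.name) for ms in all_muscle_sets()]
        note(f"muscle cohort: {len(combos)} combinations at features {fs_fixed.name}")

    combo_seeds = seed_rng.integers(0, 2**31 - 1, size=len(combos))
    records = []
    for (ms, fs, name), cseed in zip(combos, combo_seeds):
        cseed = int(cseed)
        pos_spec = replace(config.pos_model, seed=cseed)
        mom_spec = replace(config.mom_model, seed=cseed)
        record, _ = evaluate_combination(
            trials,
            split,
            ms,
            fs,
            config.window,
            pos_spec,
            mom_spec,
            alpha=config.alpha,
            seed=cseed,
            combo_name=name,
            spm_method=config.spm_method,
            n_permutations=config.n_permutations,
        )
        records.append(record)
        note(
            f"combo {name} seed={cseed}: r_pos={record.r_pos_mean:.4f} "
            f"r_mom={record.r_mom_mean:.4f}"
        )

    scores = finalize_scores(records)
    table = rank_variations(records, scores, cohort=config.cohort)

    paths: dict[str, Path] = {}
    ranking_csv = out_dir / "ranking.csv"
    table.to_dataframe().to_csv(ranking_csv, index=False, float_format="%.4f")
    paths["ranking"] = ranking_csv
    note(f"wrote {ranking_csv}")

    selection: VariationSelection | None = None
    if config.cohort == "muscle_selection":
        selection_json = out_dir / "selection.json"
        try:
            selection = select_variations(table, r_threshold=config.r_threshold)
            payload = dataclasses.asdict(selection)
            note(
                f"selection: economic={selection.economic} "
                f"flexible={selection.flexible} practical={selection.practical}"
            )
        except EmptySelectionError as exc:
            payload = {"error": str(exc), "which": exc.which, "audit": exc.audit}
            note(f"selection failed: {exc}")
        selection_json.write_text(json.dumps(payload, indent=1))
        paths["selection"] = selection_json

    log_path = out_dir / "pipeline.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    paths["log"] = log_path
    return table, selection, paths
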