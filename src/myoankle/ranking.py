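"""End-to-end combination evaluation, ranking, and variation selection.

Every candidate input combination (a feature subset at fixed muscles, or a
muscle subset at fixed features) is trained and evaluated with the same
split and seeds, scored with the composite error scores, and ranked by
ascending overall error score.  For muscle cohorts three named variations
are then selected:

    economic   - among combinations whose mean validation r reaches the
                 strong-correlation threshold (default 0.90) for BOTH
                 targets, the one with the fewest muscles (best rank wins);
    flexible   - among combinations ranked strictly better than the
                 economic one, the one with the fewest lower-leg muscles
                 (best rank wins);
    practical  - among threshold-eligible combinations containing no
                 lower-leg muscle, the one with the fewest muscles
                 (best rank wins).

Each selection records an audit trail of every filter step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .combinations import FeatureSet, MuscleSet
from .errors import EmptySelectionError, ValidationError
from .evaluation import (
    EvaluationRecord,
    ScoreRecord,
    miscorrelation_score,
    overall_error_score,
    resample_series_cycles,
    resample_to_gait_cycle,
    rmse_score,
    round_report,
    spm_f_test,
    spm_score,
    trial_agreement,
)
from .features import WindowSpec, extract_feature_matrix
from .predictor import (
    ModelSpec,
    SplitPlan,
    predict_series,
    train_predictor,
)
from .synthetic_gait import GaitTrial

__all__ = [
    "RankRow",
    "RankingTable",
    "VariationSelection",
    "evaluate_combination",
    "finalize_scores",
    "rank_variations",
    "select_variations",
]


@dataclass(frozen=True)
class RankRow:
    rank: int
    combo_name: str
    record: EvaluationRecord
    score: ScoreRecord


@dataclass
class RankingTable:
    """Combinations ordered by ascending overall error score."""

    rows: list[RankRow]
    cohort: str  # "feature_selection" | "muscle_selection"

    def __post_init__(self):
        if self.cohort not in ("feature_selection", "muscle_selection"):
            raise ValidationError("cohort must be feature_selection or muscle_selection")
        ranks = [r.rank for r in self.rows]
        if ranks != list(range(1, len(self.rows) + 1)):
            raise ValidationError("ranks must be contiguous 1..N")
        overall = [r.score.overall_error_score for r in self.rows]
        if any(b < a for a, b in zip(overall, overall[1:])):
            raise ValidationError("overall error score must be non-decreasing with rank")
        names = [r.combo_name for r in self.rows]
        if len(set(names)) != len(names):
            raise ValidationError("combo names must be unique")

    def to_dataframe(self) -> pd.DataFrame:
        """Report table mirroring the evaluation columns, rounded to 4 decimals."""
        recs = []
        for row in self.rows:
            e, s = row.record, row.score
            recs.append(
                {
                    "rank": row.rank,
                    "combination": row.combo_name,
                    "r_pos_mean": round_report(e.r_pos_mean),
                    "r_pos_sd": round_report(e.r_pos_sd),
                    "r_mom_mean": round_report(e.r_mom_mean),
                    "r_mom_sd": round_report(e.r_mom_sd),
                    "rmse_pos_deg": round_report(e.rmse_pos_mean),
                    "rmse_pos_sd": round_report(e.rmse_pos_sd),
                    "rmse_mom_nm_per_kg": round_report(e.rmse_mom_mean),
                    "rmse_mom_sd": round_report(e.rmse_mom_sd),
                    "spm_pos_frac": round_report(e.spm_frac_pos),
                    "spm_mom_frac": round_report(e.spm_frac_mom),
                    "miscorrelation_score": round_report(s.miscorrelation_score),
                    "rmse_score": round_report(s.rmse_score),
                    "spm_score": round_report(s.spm_score),
                    "overall_error_score": round_report(s.overall_error_score),
                }
            )
        return pd.DataFrame(recs)


@dataclass
class VariationSelection:
    """The economic / flexible / practical picks with their audit trail."""

    economic: str
    flexible: str
    practical: str
    audit: dict = field(default_factory=dict)


def _evaluate_trial_curves(
    trial: GaitTrial,
    fm,
    pred_pos: np.ndarray,
    pred_mom: np.ndarray,
):
    """Per-cycle %GC curves of actual and predicted series for one trial.

    The first cycle is excluded: its opening samples precede the first
    complete feature window (warm-up) and carry no prediction.
    """
    cycles = range(1, trial.n_cycles)
    if len(list(cycles)) < 1:
        raise ValidationError("trial must contain at least 2 complete cycles")
    event_times = trial.events / trial.fs_mech
    act_pos = np.array([resample_to_gait_cycle(trial.angle, trial.events, k) for k in cycles])
    act_mom = np.array([resample_to_gait_cycle(trial.moment, trial.events, k) for k in cycles])
    prd_pos = resample_series_cycles(fm.window_end_times, pred_pos, event_times, cycles)
    prd_mom = resample_series_cycles(fm.window_end_times, pred_mom, event_times, cycles)
    return act_pos, act_mom, prd_pos, prd_mom


def evaluate_combination(
    trials: Sequence[GaitTrial],
    split: SplitPlan,
    ms: MuscleSet,
    fs: FeatureSet,
    wspec: WindowSpec,
    pos_spec: ModelSpec,
    mom_spec: ModelSpec,
    alpha: float = 0.05,
    seed: int = 0,
    combo_name: str | None = None,
    spm_method: str = "permutation",
    n_permutations: int = 1000,
) -> tuple[EvaluationRecord, dict]:
    """Train, predict and evaluate one input combination.

    Trains the position and moment predictors on the training side, predicts
    every validation trial, resamples both series to %GC, and computes
    Pearson r and RMSE per validation trial (over the trial's concatenated
    resampled cycles) plus the two SPM significant-node fractions over the
    pooled per-cycle curves.

    Returns the EvaluationRecord and the cohort-independent partial scores
    (miscorrelation and SPM); the RMSE and overall scores need the full
    cohort's peaks and are computed by ``finalize_scores``.
    """
    by_id = {t.trial_id: t for t in trials}
    train = [by_id[i] for i in split.train_ids]
    valid = [by_id[i] for i in split.valid_ids]

    pos_model = train_predictor(train, ms, fs, wspec, pos_spec)
    mom_model = train_predictor(train, ms, fs, wspec, mom_spec)

    r_pos, r_mom, rmse_pos, rmse_mom = [], [], [], []
    curves = {"act_pos": [], "act_mom": [], "prd_pos": [], "prd_mom": []}
    for t in valid:
        fm = extract_feature_matrix(t, ms, fs, wspec)
        pred_pos = predict_series(pos_model, fm)
        pred_mom = predict_series(mom_model, fm)
        act_pos, act_mom, prd_pos, prd_mom = _evaluate_trial_curves(t, fm, pred_pos, pred_mom)
        r, e = trial_agreement(prd_pos.ravel(), act_pos.ravel())
        r_pos.append(r)
        rmse_pos.append(e)
        r, e = trial_agreement(prd_mom.ravel(), act_mom.ravel())
        r_mom.append(r)
        rmse_mom.append(e)
        curves["act_pos"].append(act_pos)
        curves["act_mom"].append(act_mom)
        curves["prd_pos"].append(prd_pos)
        curves["prd_mom"].append(prd_mom)

    def _sd(v):
        return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0

    spm_pos = spm_f_test(
        np.vstack(curves["act_pos"]),
        np.vstack(curves["prd_pos"]),
        alpha=alpha,
        method=spm_method,
        n_permutations=n_permutations,
        seed=seed,
    )
    spm_mom = spm_f_test(
        np.vstack(curves["act_mom"]),
        np.vstack(curves["prd_mom"]),
        alpha=alpha,
        method=spm_method,
        n_permutations=n_permutations,
        seed=seed + 1,
    )

    record = EvaluationRecord(
        combo_name=combo_name or f"{ms.name}|{fs.name}",
        r_pos_mean=float(np.mean(r_pos)),
        r_pos_sd=_sd(r_pos),
        r_mom_mean=float(np.mean(r_mom)),
        r_mom_sd=_sd(r_mom),
        rmse_pos_mean=float(np.mean(rmse_pos)),
        rmse_pos_sd=_sd(rmse_pos),
        rmse_mom_mean=float(np.mean(rmse_mom)),
        rmse_mom_sd=_sd(rmse_mom),
        spm_frac_pos=spm_pos.fraction,
        spm_frac_mom=spm_mom.fraction,
    )
    partial = {
        "miscorrelation_score": miscorrelation_score(record.r_pos_mean, record.r_mom_mean),
        "spm_score": spm_score(record.spm_frac_pos, record.spm_frac_mom),
    }
    return record, partial


def finalize_scores(records: Sequence[EvaluationRecord]) -> list[ScoreRecord]:
    """Complete the composite scores once the whole cohort is evaluated."""
    e_scores = rmse_score(records)
    out = []
    for rec, e in zip(records, e_scores):
        m = miscorrelation_score(rec.r_pos_mean, rec.r_mom_mean)
        s = spm_score(rec.spm_frac_pos, rec.spm_frac_mom)
        out.append(
            ScoreRecord(
                combo_name=rec.combo_name,
                miscorrelation_score=m,
                rmse_score=e,
                spm_score=s,
                overall_error_score=overall_error_score(m, e, s),
            )
        )
    return out


def _combo_size(name: str) -> int:
    return len(name.replace(" ", "").split("+"))


def rank_variations(
    records: Sequence[EvaluationRecord],
    scores: Sequence[ScoreRecord],
    cohort: str,
) -> RankingTable:
    """Ascending sort on overall error score; ties break on (size, name)."""
    if len(records) != len(scores):
        raise ValidationError("records and scores must pair up")
    pairs = sorted(
        zip(records, scores),
        key=lambda p: (p[1].overall_error_score, _combo_size(p[0].combo_name), p[0].combo_name),
    )
    rows = [
        RankRow(rank=i + 1, combo_name=rec.combo_name, record=rec, score=sc)
        for i, (rec, sc) in enumerate(pairs)
    ]
    return RankingTable(rows=rows, cohort=cohort)


def select_variations(table: RankingTable, r_threshold: float = 0.90) -> VariationSelection:
    """Select the economic, flexible and practical muscle variations.

    Eligibility means mean validation r >= ``r_threshold`` for BOTH targets.
    """
    if table.cohort != "muscle_selection":
        raise ValidationError("variation selection applies to muscle-selection cohorts")
    audit: dict = {"r_threshold": r_threshold}

    def eligible(row: RankRow) -> bool:
        return (
            row.record.r_pos_mean >= r_threshold and row.record.r_mom_mean >= r_threshold
        )

    rows = table.rows
    elig = [r for r in rows if eligible(r)]
    audit["eligible"] = [r.combo_name for r in elig]
    if not elig:
        raise EmptySelectionError("economic", audit)

    # economic: eligible, minimum muscle count, best rank
    min_size = min(len(MuscleSet.parse(r.combo_name)) for r in elig)
    econ_pool = [r for r in elig if len(MuscleSet.parse(r.combo_name)) == min_size]
    economic = min(econ_pool, key=lambda r: r.rank)
    audit["economic"] = {
        "min_muscle_count": min_size,
        "candidates": [r.combo_name for r in econ_pool],
        "picked": economic.combo_name,
        "rank": economic.rank,
    }

    # flexible: strictly better rank than economic, minimum lower-leg count, best rank
    better = [r for r in rows if r.rank < economic.rank]
    if not better:
        raise EmptySelectionError("flexible", audit)
    min_lower = min(MuscleSet.parse(r.combo_name).n_lower for r in better)
    flex_pool = [r for r in better if MuscleSet.parse(r.combo_name).n_lower == min_lower]
    flexible = min(flex_pool, key=lambda r: r.rank)
    audit["flexible"] = {
        "better_than_economic": len(better),
        "min_lower_leg_count": min_lower,
        "candidates": [r.combo_name for r in flex_pool],
        "picked": flexible.combo_name,
        "rank": flexible.rank,
    }

    # practical: eligible, upper-leg only, minimum muscle count, best rank
    upper_only = [r for r in elig if MuscleSet.parse(r.combo_name).n_lower == 0]
    audit["practical_upper_only_eligible"] = [r.combo_name for r in upper_only]
    if not upper_only:
        raise EmptySelectionError("practical", audit)
    min_up_size = min(len(MuscleSet.parse(r.combo_name)) for r in upper_only)
    prac_pool = [r for r in upper_only if len(MuscleSet.parse(r.combo_name)) == min_up_size]
    practical = min(prac_pool, key=lambda r: r.rank)
    audit["practical"] = {
        "min_muscle_count": min_up_size,
        "candidates": [r.combo_name for r in prac_pool],
        "picked": practical.combo_name,
        "rank": practical.rank,
    }

    return VariationSelection(
        economic=economic.combo_name,
        flexible=flexible.combo_name,
        practical=practical.combo_name,
        audit=audit,
    )
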