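"""LSTM regressors from sEMG feature sequences to ankle angle and moment.

Two separate single-output networks are used — one for sagittal ankle
position (deg), one for body-mass-normalized moment (Nm/kg) — rather than a
single two-output network, keeping each model small enough to tune
independently.  Defaults follow the study design: Adam, 200 epochs, 200
hidden units for position and 50 for moment, with the hidden-unit count
selectable by a validation sweep over candidates up to 250.

Inputs and target are z-scored by training-set statistics.  This
standardizes network inputs only; the scalers are fixed constants of the
trained model and do not reintroduce sEMG amplitude normalization (no
reference contraction or per-trial rescaling is involved).

Training cuts each trial's feature sequence into truncated subsequences
(default 100 rows = 1 s) for bounded-memory backpropagation through time;
inference runs statefully over the full trial sequence.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._lstm import LSTMCore
from .combinations import FeatureSet, MuscleSet
from .errors import AlignmentError, ContractError, ValidationError
from .features import FeatureMatrix, WindowSpec, extract_feature_matrix
from .synthetic_gait import GaitTrial

__all__ = [
    "ModelSpec",
    "Scaler",
    "TrainedPredictor",
    "SplitPlan",
    "make_split",
    "align_targets",
    "train_predictor",
    "predict_series",
    "hidden_unit_sweep",
    "save_predictor",
    "load_predictor",
]

TARGETS = ("position", "moment")
DEFAULT_HIDDEN = {"position": 200, "moment": 50}


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of one LSTM regressor."""

    target: str
    hidden_units: int | None = None
    epochs: int = 200
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    sequence_length: int = 100
    batch_size: int = 16
    grad_clip: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.target not in TARGETS:
            raise ValidationError(f"target must be one of {TARGETS}")
        if self.hidden_units is None:
            object.__setattr__(self, "hidden_units", DEFAULT_HIDDEN[self.target])
        if not 1 <= self.hidden_units <= 250:
            raise ValidationError("hidden_units must lie in [1, 250]")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValidationError("only the adam optimizer is supported")
        if self.sequence_length < 1 or self.batch_size < 1:
            raise ValidationError("sequence_length and batch_size must be >= 1")


@dataclass
class Scaler:
    """Invertible per-column affine standardization: z = (x - center) / scale."""

    center: np.ndarray
    scale: np.ndarray

    def __post_init__(self):
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        self.scale = np.atleast_1d(np.asarray(self.scale, dtype=float))
        if np.any(self.scale <= 0):
            raise ValidationError("scaler scale entries must be > 0")

    @classmethod
    def fit(cls, x: np.ndarray, context: str = "input") -> "Scaler":
        x = np.atleast_2d(np.asarray(x, dtype=float))
        center = x.mean(axis=0)
        scale = x.std(axis=0)
        degenerate = scale == 0
        if np.any(degenerate):
            warnings.warn(
                f"{context}: {int(degenerate.sum())} zero-variance column(s); scale set to 1",
                stacklevel=2,
            )
            scale = np.where(degenerate, 1.0, scale)
        return cls(center=center, scale=scale)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.center) / self.scale

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return z * self.scale + self.center


@dataclass
class TrainedPredictor:
    """One trained LSTM regressor with its contract and provenance."""

    spec: ModelSpec
    core: LSTMCore
    input_scaler: Scaler
    target_scaler: Scaler
    input_columns: tuple[tuple[str, str], ...]
    training_log: list[float]

    @property
    def weights_checksum(self) -> str:
        return self.core.checksum()


@dataclass(frozen=True)
class SplitPlan:
    """Trial-level train/validation partition."""

    train_ids: tuple[str, ...]
    valid_ids: tuple[str, ...]
    fraction: float
    seed: int

    def __post_init__(self):
        if set(self.train_ids) & set(self.valid_ids):
            raise ValidationError("train and validation ids must be disjoint")
        if not self.train_ids or not self.valid_ids:
            raise ValidationError("both split sides must be non-empty")


def _trial_ids(trials: Sequence) -> list[str]:
    return [t if isinstance(t, str) else t.trial_id for t in trials]


def make_split(trials: Sequence, fraction: float = 0.80, seed: int = 0) -> SplitPlan:
    """Random trial-level split (never within a trial); deterministic under seed.

    The training side gets round(fraction * n) trials, clamped so both sides
    stay non-empty (e.g., 844 trials at 0.8 -> 675 training).
    """
    ids = _trial_ids(trials)
    if len(ids) < 2:
        raise ValidationError("need at least 2 trials to split")
    if len(set(ids)) != len(ids):
        raise ValidationError("trial ids must be unique")
    if not 0 < fraction < 1:
        raise ValidationError("fraction must lie in (0, 1)")
    n_train = int(round(fraction * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    order = np.random.default_rng(seed).permutation(len(ids))
    train = tuple(ids[i] for i in sorted(order[:n_train]))
    valid = tuple(ids[i] for i in sorted(order[n_train:]))
    return SplitPlan(train_ids=train, valid_ids=valid, fraction=fraction, seed=seed)


def align_targets(trial: GaitTrial, fm: FeatureMatrix, target: str = "position") -> np.ndarray:
    """Target values linearly interpolated to each feature window end time."""
    if target not in TARGETS:
        raise ValidationError(f"target must be one of {TARGETS}")
    series = trial.angle if target == "position" else trial.moment
    t_mech = np.arange(len(series)) / trial.fs_mech
    t = fm.window_end_times
    tol = 1e-9
    if t[0] < t_mech[0] - tol or t[-1] > t_mech[-1] + tol:
        raise AlignmentError(
            f"window times [{t[0]:g}, {t[-1]:g}] exceed mechanical span "
            f"[{t_mech[0]:g}, {t_mech[-1]:g}]"
        )
    return np.interp(np.clip(t, t_mech[0], t_mech[-1]), t_mech, series)


def _sequences(x: np.ndarray, y: np.ndarray, length: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Cut one trial into non-overlapping subsequences; a trial shorter than
    ``length`` becomes a single shorter sequence, trailing remainders are dropped."""
    n = len(y)
    if n <= length:
        return [(x, y)]
    return [(x[s : s + length], y[s : s + length]) for s in range(0, n - length + 1, length)]


def train_predictor(
    train_trials: Sequence[GaitTrial],
    ms: MuscleSet,
    fs: FeatureSet,
    wspec: WindowSpec,
    spec: ModelSpec,
) -> TrainedPredictor:
    """Train one LSTM regressor on the training trials.

    Features and target are z-scored by training-set statistics; MSE loss;
    Adam; truncated subsequences of ``spec.sequence_length`` rows, batched by
    equal length.  ``training_log`` holds the mean training MSE of each epoch
    (in z-scored units).  Deterministic given ``spec.seed``.
    """
    if not train_trials:
        raise ValidationError("need at least one training trial")
    mats = [extract_feature_matrix(t, ms, fs, wspec) for t in train_trials]
    targets = [align_targets(t, m, spec.target) for t, m in zip(train_trials, mats)]

    x_all = np.vstack([m.values for m in mats])
    y_all = np.concatenate(targets)
    input_scaler = Scaler.fit(x_all, context=f"{spec.target} inputs")
    target_scaler = Scaler.fit(y_all[:, None], context=f"{spec.target} target")

    seqs: list[tuple[np.ndarray, np.ndarray]] = []
    for m, y in zip(mats, targets):
        xz = input_scaler.transform(m.values)
        yz = target_scaler.transform(y[:, None])[:, 0]
        seqs.extend(_sequences(xz, yz, spec.sequence_length))

    rng = np.random.default_rng(spec.seed)
    core = LSTMCore(
        n_inputs=x_all.shape[1],
        hidden_units=spec.hidden_units,
        rng=rng,
        learning_rate=spec.learning_rate,
        grad_clip=spec.grad_clip,
    )

    # batches of equal sequence length only
    by_length: dict[int, list[int]] = {}
    for idx, (sx, _) in enumerate(seqs):
        by_length.setdefault(len(sx), []).append(idx)

    training_log: list[float] = []
    for _ in range(spec.epochs):
        losses, weights = [], []
        for length in sorted(by_length):
            idxs = np.array(by_length[length])
            rng.shuffle(idxs)
            for start in range(0, len(idxs), spec.batch_size):
                chunk = idxs[start : start + spec.batch_size]
                bx = np.stack([seqs[i][0] for i in chunk])
                by = np.stack([seqs[i][1] for i in chunk])
                losses.append(core.train_batch(bx, by))
                weights.append(len(chunk) * length)
        training_log.append(float(np.average(losses, weights=weights)))

    return TrainedPredictor(
        spec=spec,
        core=core,
        input_scaler=input_scaler,
        target_scaler=target_scaler,
        input_columns=tuple(
            (m, f) for m, f in mats[0].columns
        ),
        training_log=training_log,
    )


def predict_series(p: TrainedPredictor, fm: FeatureMatrix) -> np.ndarray:
    """Predict the target series for one trial's feature matrix (original units)."""
    if tuple(fm.columns) != p.input_columns:
        raise ContractError(
            f"feature columns {fm.column_names} do not match the trained contract"
        )
    z = p.input_scaler.transform(fm.values)
    yz = p.core.predict(z)
    y = p.target_scaler.inverse(yz[:, None])[:, 0]
    if not np.all(np.isfinite(y)):
        raise ContractError("prediction produced non-finite values")
    return y


def hidden_unit_sweep(
    train_trials: Sequence[GaitTrial],
    valid_trials: Sequence[GaitTrial],
    ms: MuscleSet,
    fs: FeatureSet,
    wspec: WindowSpec,
    candidates: Sequence[int],
    base_spec: ModelSpec,
) -> tuple[int, pd.DataFrame]:
    """Validation sweep over hidden-unit counts.

    Trains one model per candidate (shared seed) and returns the candidate
    with the highest mean validation Pearson r (ties -> smaller count),
    together with the per-candidate table.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValidationError("candidates must be non-empty")
    if any(c > 250 or c < 1 for c in candidates):
        raise ValidationError("every candidate must lie in [1, 250]")
    rows = []
    for c in candidates:
        spec = replace(base_spec, hidden_units=c)
        model = train_predictor(train_trials, ms, fs, wspec, spec)
        rs = []
        for t in valid_trials:
            fm = extract_feature_matrix(t, ms, fs, wspec)
            pred = predict_series(model, fm)
            actual = align_targets(t, fm, spec.target)
            rs.append(stats.pearsonr(pred, actual).statistic)
        rows.append({"hidden_units": c, "mean_valid_r": float(np.mean(rs))})
    table = pd.DataFrame(rows)
    best_r = table["mean_valid_r"].max()
    best = int(table.loc[table["mean_valid_r"] == best_r, "hidden_units"].min())
    return best, table


ARCHIVE_VERSION = "myoankle-predictor-1"


def save_predictor(p: TrainedPredictor, path: str | Path) -> None:
    """Single-file archive: spec JSON + scaler JSON + weight arrays, version-tagged."""
    meta = {
        "version": ARCHIVE_VERSION,
        "spec": dataclasses.asdict(p.spec),
        "input_columns": list(p.input_columns),
        "training_log": p.training_log,
        "scalers": {
            "input_center": p.input_scaler.center.tolist(),
            "input_scale": p.input_scaler.scale.tolist(),
            "target_center": p.target_scaler.center.tolist(),
            "target_scale": p.target_scaler.scale.tolist(),
        },
    }
    arrays = {f"w_{n}": a for n, a in p.core.state_arrays().items()}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_predictor(path: str | Path) -> TrainedPredictor:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["meta"]).decode())
        if meta.get("version") != ARCHIVE_VERSION:
            raise ValidationError(f"unsupported archive version: {meta.get('version')!r}")
        spec = ModelSpec(**meta["spec"])
        core = LSTMCore(
            n_inputs=len(meta["input_columns"]),
            hidden_units=spec.hidden_units,
            rng=np.random.default_rng(0),
            learning_rate=spec.learning_rate,
            grad_clip=spec.grad_clip,
        )
        core.load_state({n: archive[f"w_{n}"] for n in LSTMCore.PARAM_NAMES})
    sc = meta["scalers"]
    return TrainedPredictor(
        spec=spec,
        core=core,
        input_scaler=Scaler(np.array(sc["input_center"]), np.array(sc["input_scale"])),
        target_scaler=Scaler(np.array(sc["target_center"]), np.array(sc["target_scale"])),
        input_columns=tuple((m, f) for m, f in meta["input_columns"]),
        training_log=list(meta["training_log"]),
    )
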