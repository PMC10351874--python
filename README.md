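# myoankle

Tools for developing and ranking surface-EMG-driven predictors of sagittal
ankle kinematics and kinetics during level walking — the algorithmic core of
a myoelectric powered-ankle-prosthesis controller.

## The problem

A powered ankle prosthesis needs continuous estimates of the ankle's intended
angle (deg) and body-mass-normalized moment (Nm/kg). Surface EMG (sEMG) of
leg muscles carries that intent, but real-time use rules out amplitude
normalization (the reference contraction drifts with fatigue, electrode
impedance and walking speed), and every extra electrode adds cost and setup
complexity. Two questions follow:

1. Can ankle angle and moment be regressed from **nonnormalized** sEMG,
   using only short-window time-domain features?
2. Which electrode (muscle) subsets give the best trade-off between accuracy
   and sensor count?

`myoankle` answers both with an exhaustive, fully seeded pipeline over eight
muscles — tibialis anterior (TA), soleus (SO), medial gastrocnemius (MG),
peroneus longus (PL) on the lower leg; rectus femoris (RF), vastus medialis
(VM), biceps femoris (BF), gluteus maximus (GMax) on the upper leg — and
five window features.

## Method

**Features.** Over causal sliding windows x₁..x_N (150 ms window, 10 ms hop)
of each raw sEMG channel:

- IEMG = Σ|xₙ|, MAV = (1/N)Σ|xₙ|, RMS = √((1/N)Σxₙ²),
- WL = Σ|xₙ₊₁ − xₙ|, WAMP = #{n : |xₙ − xₙ₊₁| ≥ threshold}.

**Regression.** Two separate single-layer LSTM networks with a linear head
(one for angle, one for moment; defaults 200 and 50 hidden units), trained
with Adam on z-scored inputs/targets for 200 epochs, with a validation sweep
over hidden-unit counts up to 250. Trials are split 80/20 at the trial level.

**Evaluation.** Predictions and references are resampled per gait cycle onto
a 100-node %GC grid. Per combination: Pearson r and RMSE per validation
trial (mean ± SD), and a 1-D SPM two-group F test localizing the %GC nodes
where predicted and reference curve populations differ (family-wise
threshold by a seeded permutation max-statistic).

**Ranking.** Combinations are ranked by the *overall error score*

    overall = miscorrelation × RMSE-score × SPM-score

with miscorrelation = ((1−r_pos)+(1−r_mom))/2, RMSE-score the mean of the two
RMSEs normalized to their cohort peaks, SPM-score the mean significant-node
fraction. From a muscle-cohort ranking three variations are selected:
**economic** (fewest muscles among combinations with mean r ≥ 0.90 for both
targets), **flexible** (fewest lower-leg muscles among combinations ranked
better than the economic one), and **practical** (fewest muscles among
eligible upper-leg-only combinations).

A seeded synthetic gait generator (phase-locked, speed-scaled activation
envelopes modulating band-limited 10–400 Hz noise carriers, plus smooth
periodic ankle angle/moment templates, speeds 0.3–2.3 m/s) makes the whole
pipeline testable end to end without any recorded data. See
`docs/methods.md` for the model details and design choices.

## Worked example

Noise-free synthetic recovery: 20 trials, all 8 muscles, IEMG+WL features,
reduced training (32 hidden units, 5 epochs):

```python
import numpy as np
from scipy import stats
from myoankle import (
    SynthConfig, MuscleSet, FeatureSet, WindowSpec, ModelSpec,
    generate_dataset, make_split, train_predictor, predict_series,
    extract_feature_matrix, align_targets, miscorrelation_score,
)

config = SynthConfig(noise_floor=0.0, angle_noise_sd=0.0, moment_noise_sd=0.0)
trials = generate_dataset(config, n_trials=20, seed=1)
split = make_split(trials, fraction=0.8, seed=1)
train = [t for t in trials if t.trial_id in split.train_ids]
valid = [t for t in trials if t.trial_id in split.valid_ids]

muscles = MuscleSet(["TA", "SO", "MG", "PL", "RF", "VM", "BF", "GMax"])
features = FeatureSet(["IEMG", "WL"])
wspec = WindowSpec()  # 150 ms window, 10 ms hop

mean_r = {}
for target in ("position", "moment"):
    spec = ModelSpec(target=target, hidden_units=32, epochs=5, seed=1)
    model = train_predictor(train, muscles, features, wspec, spec)
    rs = [
        stats.pearsonr(
            predict_series(model, fm := extract_feature_matrix(t, muscles, features, wspec)),
            align_targets(t, fm, target),
        ).statistic
        for t in valid
    ]
    mean_r[target] = np.mean(rs)
    print(f"{target}: mean validation r = {mean_r[target]:.4f}")

print(f"miscorrelation score = "
      f"{miscorrelation_score(mean_r['position'], mean_r['moment']):.4f}")
```

prints

```
position: mean validation r = 0.9350
moment: mean validation r = 0.9725
miscorrelation score = 0.0462
```

i.e., the windowed-feature → LSTM pipeline recovers both targets with strong
validation correlations, and their mean deviation from perfect correlation
is 0.0462.

The full cohort pipeline is available from the shell:

```sh
myoankle rank --cohort feature_selection --n-trials 8 --epochs 2 \
    --seed 7 --out-dir out/
myoankle report --ranking-csv out/ranking.csv
```

which ranks all 31 feature combinations at the fixed MG+BF+GMax muscle set
(use `--cohort muscle_selection` for all 255 muscle subsets at fixed IEMG+WL,
including the economic/flexible/practical selection with its audit trail).

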