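# dichotic

Simulation and single-trial analysis of two neural "attentional filter"
mechanisms in dichotic (dual-talker) listening: **alpha-power
lateralization** and **neural speech tracking** by backward
(stimulus-reconstruction) models — plus the state/trait mixed-effects
machinery that links both to listening behaviour.

It is aimed at auditory cognitive-neuroscience researchers who want a
tested, ground-truth-verified reference implementation of this analysis
chain: every stage runs on a synthetic dichotic-listening dataset with
planted effects, so decoder weights, lateralization indices, temporal
delays, odds ratios and standardized betas can all be checked by parameter
recovery.

## What it computes

Given per-trial bilateral auditory source signals r(t, n) and the onset
envelopes s(t) of the two speech streams:

- **Alpha lateralization index (ALI).** Morlet power (8–12 Hz, 6 cycles)
  → Box-Cox `(x^p − 1)/p`, p = 0.5 → whole-trial normalization per
  parcel × frequency → ROI average → robust index
  `ALI = (σ(P_ipsi) − σ(P_contra)) / (σ(P_ipsi) + σ(P_contra))`
  with σ the inverse-logit and hemispheres labelled by the probed ear.
- **Backward decoding.** ŝ(t) = Σ_n Σ_τ g(τ, n) r(t + τ, n) with lags
  −100…500 ms, ridge solution `g = (RᵀR + λ m I)⁻¹ Rᵀ s` (m = mean trace
  of RᵀR; λ selected on the grid 10⁻⁵…10¹⁰ by cross-validated sliding
  correlation). Attended/ignored decoders per attend side, leave-one-out
  reconstruction, 248 ms sliding Pearson correlation, and the
  **neural tracking index** `(r_att − r_ign)/(r_att + r_ign)`; backward
  weights are forward-transformed via `A = Cov(R) g / Var(ŝ)`.
- **Temporal alignment.** Per-trial series warped to 100 percent-of-
  sentence bins (3-bin smoothing), final-word summaries (last 35%), and
  the cross-correlation of grand-average tracking and ALI time courses
  with a 5000-permutation surrogate band.
- **Behaviour.** Accuracy (binomial-logit) and response-speed (Gaussian)
  mixed models with subject and item random intercepts, deviation coding,
  within/between (state/trait) decomposition of neural regressors, Wald
  tests, BH-FDR at q = 5%, and likelihood-ratio tests for random slopes
  (estimated with lme4 via `Rscript`).

See `docs/methods.md` for assumptions, parameter defaults, and design
choices.

## Worked example

```python
from dichotic.config import PipelineConfig, SimulationConfig, TemporalConfig
from dichotic.pipeline import run_all

cfg = PipelineConfig(
    simulation=SimulationConfig(n_subjects=4, n_trials_per_cell=10),
    temporal=TemporalConfig(n_permutations=1000),
)
report = run_all(cfg, "out", seed=42)
print(report["behaviour"])
print(report["tracking"])
```

prints (numbers from this exact run):

```
{'n_trials': 160, 'mean_accuracy_pct': 85.16, 'mean_rt_ms': 1853.8, 'mean_speed': 0.591}
{'mean_nti_final': 0.0787, 'mean_r_attended': 0.835, 'mean_r_ignored': 0.769}
```

The simulated cohort answers ~85% of probes correctly; the attended
stream's envelope reconstructs better than the ignored one (0.835 vs.
0.769 mean sliding correlation), giving a positive mean tracking index
over the final-word interval. `out/model_accuracy.csv` holds the fitted
accuracy model; at this toy scale (160 trials) the spatial-cue odds ratio
is estimated at 5.5 with SE 0.87 on the log scale — consistent with the
planted odds ratio of 3.5, whose precise recovery needs the full 50
subjects × 240 trials used by the acceptance checks. The same run writes
the alpha feature table, per-trial tracking table, warped group time
courses, the cross-correlation with its surrogate band, and a JSON report.

The identical analysis is available stage by stage from the shell:

```bash
dichotic simulate  --seed 42 --out out
dichotic features  --seed 42 --out out
dichotic decode    --seed 42 --out out
...
dichotic report    --seed 42 --out out     # or: dichotic all --seed 42 --out out
```

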