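# gazeddm

Gaze-weighted drift-diffusion modelling of multi-attribute dietary choice
under different hunger states.

## The problem

In binary food choice, people trade off how *tasty* and how *healthy* two
options are, and where they look matters: evidence for an option accumulates
faster while it (and in particular one of its attributes) is being fixated.
`gazeddm` implements a nested family of evidence-accumulation models for this
setting, together with everything needed to fit and criticize them on
choice + response-time + eye-tracking data from a two-session (hungry vs.
sated) within-subject design:

* **DDM** — drift proportional to the weighted value difference
  `VD = ω(T_i − T_j) + (1 − ω)(H_i − H_j)`, with taste values `T`, health
  values `H` (scaled to [1, 10] per participant) and relative taste weight
  `ω ∈ (0, 1)`.
* **aDDM** — the currently unfixated *option* is discounted by `θ`; the
  option-level dwell shares `f_i, f_j` mix the two gaze states.
* **maaDDM** — additionally discounts the unfixated *attribute* by `φ`,
  using the four option×attribute dwell shares `f_{i,T}, f_{i,H}, f_{j,T},
  f_{j,H}`.
* **maaDDM2φ** — separate attribute discounts `φ_T` and `φ_H`, so looking
  at a food image can blunt health information more than taste information:

  ```
  VD = f_iT [ω(T_i − θT_j)      + (1−ω)φ_H(H_i − θH_j)]
     + f_iH [ωφ_T(T_i − θT_j)   + (1−ω)(H_i − θH_j)]
     + f_jT [ω(θT_i − T_j)      + (1−ω)φ_H(θH_i − H_j)]
     + f_jH [ωφ_T(θT_i − T_j)   + (1−ω)(θH_i − H_j)]
  ```

Each variant also exists with a free starting point `β` (`*sp` models); the
drift is `v = d · VD` with scaling `d`, diffusion noise is fixed at 1, and
RT = first-passage time through boundaries {0 = healthy, α = tasty} plus a
non-decision time nDT.

Estimation is hierarchical Bayesian with a condition-difference scheme:
participant parameters for the sated condition ("baseline") plus an additive
raw-scale "change" under hunger, both with group-level normal/half-normal
hyperpriors; `α` and nDT pass through a softplus, `ω` and `β` through the
standard normal CDF. Convergence is gated on the Gelman-Rubin statistic
(Rhat ≤ 1.05), model comparison uses the DIC, and model criticism uses
posterior predictive RT-quantile checks and parameter-recovery studies.
A Bayesian within-subject multilevel mediation model (hunger → dwell on the
tasty option → tasty choice) completes the analysis.

Because raw lab data are not bundled, a first-class synthetic-cohort
generator reproduces the study design (66 items over five Nutri-Score
classes, slider ratings with a two-factor taste/health structure, 190 trials
per session, 4-AOI fixation streams with an image-over-score dwell bias,
choices and RTs forward-simulated from the model) with a ground-truth
sidecar, so every stage of the pipeline is testable end to end.

## Worked example

```python
from gazeddm import (CohortConfig, HierarchicalDDM, MCMCConfig,
                     gen_dataset, prepare_trials)

cfg = CohortConfig(model="maaDDM2phi", n_participants=8, n_trials=60)
trials, fixations, ratings, truth = gen_dataset(cfg, seed=3)
oriented, report = prepare_trials(trials, fixations)   # RT filter, dwell shares
print(report)

est = HierarchicalDDM(model="DDM", config=MCMCConfig(3, 2000, 1000, 2),
                      random_state=1).fit(oriented)
print(est.result_.group_posterior().head(6).round(3).to_string())
```

Output from this exact snippet (the cohort is generated from a DDM-like
truth with taste weight ω ≈ 0.77 sated, α ≈ 2.2 and nDT = 0.35 s):

```
{'n_input': 960, 'n_removed_fast': 0, 'n_removed_slow': 2, 'n_retained': 958, 'n_removed_zero_dwell': 0}
  parameter condition   mean     sd  hdi_2.5  hdi_97.5
0     alpha     sated  1.989  0.145    1.718     2.298
1     alpha    hungry  1.895  0.152    1.597     2.218
2     alpha    change -0.111  0.096   -0.298     0.081
3       ndt     sated  0.344  0.036    0.276     0.417
4       ndt    hungry  0.350  0.039    0.274     0.425
5       ndt    change  0.019  0.069   -0.110     0.156
```

Condition rows are on the interpretable (transformed) scale — boundary
separation near 2, non-decision time near 0.35 s — while the `change` rows
report the hunger effect on the raw scale, where 0 means no effect (the
95% HDIs above include 0, as they should for a parameter the generator did
not shift). `est.dic_` gives the DIC for model comparison and
`est.result_.rhat` the per-quantity convergence diagnostics.

The same pipeline is scriptable from the shell:

```bash
gazeddm simulate --out runs/sim --model maaDDM2phi --participants 8 --trials 60 --seed 3
gazeddm preprocess --data runs/sim --out runs/pre
gazeddm fit --data runs/pre --out runs/fit --model DDM --preset test --seed 1
gazeddm mediate --data runs/pre --out runs/med
```

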