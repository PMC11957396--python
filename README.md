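# gonogo

Analysis pipeline and spiking-network model for cerebellar reinforcement
learning in the Go/No-go auditory-discrimination licking task.

Mice learn to lick after a Go tone (liquid reward) and withhold licking
after a No-go tone (timeout on a false alarm). This package implements, as
tested reusable code, the computational chain that links that behavior to
cerebellar climbing-fiber activity:

1. **`gonogo.qlearning`** — a Q-learning model of the licking policy.
   The value of the realized (cue, Lick) pair is updated by the predictive
   reward-prediction error, `δQ_t = (R-P)_t − Q_t`, `Q_{t+1} = Q_t + α δQ_t`
   with `R-P = 1` (HIT), `−ξ` (false alarm), `0` (CR/MISS), and actions drawn
   by a softmax with temperature τ: `P(Lick|s) = e^{Q/τ}/(e^{Q/τ} + 1)`.
   Maximum-likelihood fitting (multi-start L-BFGS-B), per-session R², BIC and
   a nested-model ladder.
2. **`gonogo.tca`** — baseline-subtracted complex-spike PSTH tensors
   (neurons × 50 time bins × 4 cue-response conditions), non-negative CP
   decomposition `x_ntk ≈ Σ_r λ_r w_nr b_tr a_kr` by HALS, and the trial-wise
   tensor-component score `y_ij^r = w_ir a_cr Σ_s b_r(t_s)` that turns the
   factors into a generative model of single-trial spiking (with a
   synchronized-spike variant on 30-ms coincidences).
3. **`gonogo.regress`** — the ten trial-wise explanatory variables (reward R,
   Q, δQ, six cue-crossed lick counts, latency fluctuation), PLS regression
   with VIP scores (Σ VIP² = J), sparse CCA by penalized matrix decomposition
   (L1 bounds 0.4/0.6, four re-signed pairs), and mixed-effects slopes with
   mouse as random intercept.
4. **`gonogo.network`** — a 5,000-unit spiking model of the PC–CN–IO circuit:
   two cue-specific modules with shared-format parallel-fiber input,
   bidirectional PF→PC plasticity `Δw = −α(IO − ĪO)`, a lick-rate sigmoid of
   the combined CN rates, error-driven inferior-olive Poisson input, and
   CN-regulated electrical coupling on a 10×10 IO lattice,
   `g_t = g₀ − β(CN_{t−1} − CN₀)`.
5. **`gonogo.synth`** — seed-deterministic generators for behavior, planted
   CP-structure spike trains and design fixtures, so every analysis is
   testable without any recording data.

See `docs/methods.md` for the models, assumptions, calibration and known
limitations. Numbered drivers under `analysis/` run the full chain and write
tables to `results/`.

## Worked example

Run the spiking-network learning experiment (three seeded simulations of 500
trials; `analysis/04_network_experiment.py` does exactly this):

```
$ python analysis/04_network_experiment.py
stage-wise means over 3 simulations:
  lick Go     : 3.45 -> 4.42 Hz
  lick No-go  : 2.77 -> 1.16 Hz
  IO_Go  (Go trials)   : 1.49 -> 2.67 Hz
  IO_Nogo(No-go trials): 2.41 -> 1.45 Hz
  PF->PC weight Go   : 10 -> 24.9
  PF->PC weight No-go: 10 -> 0.65
  coupling g (Go)    : 5 -> 7.81
  IO_Go synchrony (Go trials): 0.000 -> 0.053
```

Reading the output: between the first and last 100 trials the model learns
to lick more after Go cues and almost stops licking after No-go cues, so
the lick-rate errors of both cues shrink toward zero. The teaching signal
carried by the inferior olive moves in opposite directions in the two
modules, which drives the bidirectional plasticity: the Go module's
parallel-fiber weight potentiates from 10 toward 25 while the No-go
module's weight depresses to near zero. Falling cerebellar-nuclei activity
in the Go module strengthens the effective electrical coupling of its
inferior-olive lattice from 5 toward 8, visible as increased spike
synchrony.

The behavioral model, by itself:

```python
import numpy as np
from gonogo import qlearning as ql

params = ql.QLearnParams(alpha=0.002, q1=0.12, q2=0.24, tau=0.14, xi=0.84)
cues = np.where(np.random.default_rng(0).random(5000) < 0.5, ql.GO, ql.NOGO)
trials, trace = ql.simulate_behavior(params, cues, rng=0)
fit = ql.fit(trials, objective_mode="loglik", seed=0)
print(fit.params.tau, fit.params.xi)   # ~0.14, ~0.84 at this sample size
```

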