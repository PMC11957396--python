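# Methods

This note documents the models implemented in `gonogo`, the assumptions
behind them, the tunable parameters and their defaults, what the synthetic
data emulate, and the numerical choices made where the published description
left the design open.

## 1. Q-learning model of licking behavior

State `s ∈ {Go, No-go}` (the auditory cue) and action `a ∈ {Lick, No-lick}`
within the 1-s response window. The reward–penalty signal is

    R-P = 1      (Go, Lick)      HIT, liquid reward
    R-P = −ξ     (No-go, Lick)   false alarm, timeout punishment, 0 ≤ ξ ≤ 1
    R-P = 0      otherwise       CR and MISS

and the state–action value of the realized pair is updated once per trial:

    δQ_t = (R-P)_t − Q_t ,   Q_{t+1} = Q_t + α δQ_t .

`Q(s, No-lick)` is identically zero and never updated — CR and MISS trials
carry neither reward nor penalty, so their value and prediction error stay
pinned at zero — and the softmax policy therefore compares `Q(s, Lick)`
against zero:

    P(Lick | s) = exp(Q/τ) / (exp(Q/τ) + 1).

Five hyperparameters with their legal ranges: learning rate α ∈ [0.001, 0.1],
initial values q₁, q₂ ∈ [0, 1] (positive because the animals were pre-trained
with both cues rewarded), temperature τ ∈ [0.01, 0.5], penalty ξ ∈ [0, 1].
There is no within-trial time course and no temporal-difference bootstrap:
δQ is a *predictive* error computed at cue time.

**Fitting.** For a fixed observed trial sequence the value trajectory has a
closed form (`Q(Go,Lick)` after m HITs is `1 − (1 − q₁)(1 − α)^m`, and
`Q(No-go,Lick)` after m FAs is `−ξ + (q₂ + ξ)(1 − α)^m`), so the objective
is evaluated without per-trial loops. Two objectives are exposed: the
literal sum of per-trial action probabilities (`sumprob`, the default) and
the log-likelihood (`loglik`), which is required for information criteria;
both are maximized by bounded multi-start L-BFGS-B (10 seeded random starts
plus the bound midpoint). BIC is `k ln n − 2 ln L` with n the trial count;
reduced models pin parameters at neutral values (ξ = 1, q₁ = q₂ shared, τ
fixed; α always free) through a configurable ladder.

**Goodness of fit.** Per session, the data probability h is the fraction
correct (Go) or fraction incorrect (No-go) and the model probability f is
P(Lick) at the session's last HIT (respectively FA) trial;
`R² = 1 − Σ(h−f)²/Σ(h−h̄)²` and may be negative. Sessions without a HIT
(resp. FA) trial are dropped from that cue's vectors; constant h raises an
error (R² undefined).

**Identifiability.** ξ enters the objective only through FA trials; with no
FA trials it is flagged non-identifiable. Even with thousands of trials, ξ
and α share a likelihood ridge when learning is slow (at α ≈ 0.002 the
No-go value trajectory only partially converges toward −ξ within a session
budget), so single-fit ξ errors of ±0.1–0.2 are expected while the median
absolute error across replicates stays near 0.04.

## 2. PSTH tensor and trial-wise component scores

Complex-spike PSTHs are built per neuron and cue-response condition over
[−0.5, 2] s with 50-ms bins (50 bins × 4 conditions), as
`count / (bin width × trial count)` minus that neuron–condition's mean rate
in the baseline window [−2, −1] s. Conditions without trials give zero rows
and are flagged. Baseline subtraction can produce negative entries; they
are clipped at zero before factorization (clipping preserves the meaning of
zero activity, unlike shifting) and the clip count is reported via a
warning.

The tensor `x_ntk` is factorized by non-negative canonical polyadic
decomposition, `x̂_ntk = Σ_r λ_r w_nr b_tr a_kr`, with every factor vector
unit Euclidean length and the scale absorbed into λ_r ≥ 0. The solver is
hierarchical alternating least squares with non-negativity projection,
restarted from (default) 10 random initializations and keeping the best
reconstruction; components are returned sorted by λ descending. Dead
components are rescued with a tiny epsilon vector rather than deleted, so
the requested rank is always returned. R = 4 components are used
throughout (the rank established for this data set in prior work); rank
selection is out of scope.

**Trial scores.** The factors act as a generative model for single trials:
the activity of neuron i on trial j (condition c) w.r.t. component r is the
spike train filtered by the component's temporal profile,

    y_ij^r = w_ir × a_cr × Σ_s b_r(t_s),

with spikes restricted to [−0.5, 2] s and b evaluated piecewise-constant at
each spike's 50-ms bin (matching the resolution at which b was estimated;
linear interpolation is available as an option). The session TC score of
trial j is the arithmetic mean of y over the session's neurons, giving four
scores per trial.

**Synchronized-spike variant.** A spike is retained if its 30-ms bin
contains spikes from at least k distinct neurons of the same session and
trial (k = 2 by default; the coincidence criterion is configurable because
pairwise vs population readings of "co-activated" both exist). Sessions
with fewer than k neurons produce empty trains with a warning.

## 3. Association analyses

**Explanatory variables (10 per trial):** physical reward R (1 iff HIT — 
distinct from the R-P signal of the value model), Q and δQ of the realized
(cue, Lick) pair, lick counts in the early [0, 0.5] s, reward [0.5, 2] s and
late [2, 4] s windows crossed with cue (zero for the other cue), and the
lick-latency fluctuation |latency − mouse mean latency|, computed separately
for HIT and FA trials and imputed for MISS (resp. CR) trials with the
mouse's HIT (resp. FA) mean. All columns are standardized (mean 0, sd 1)
before any fit; constant columns are rejected.

**PLS + VIP.** Y (zone activity or TC scores) is regressed on the ten
variables by PLS (scikit-learn NIPALS); the component count F minimizes
10-fold cross-validated prediction error. Variable importance in projection:

    VIP_j = sqrt( J · Σ_f ss_f (w_jf/‖w_f‖)² / Σ_f ss_f ),

the standard normalization under which Σ_j VIP_j² = J and VIP > 1 marks an
important predictor. (A variant that additionally divides by F is available
behind `normalization="literal"`; it breaks the sum identity and is not the
default because the VIP > 1 threshold presumes the standard form.) VIP
carries no sign information.

**Sparse CCA.** Penalized matrix decomposition of the cross-covariance with
binary-searched soft-thresholding, L1 bounds expressed as fractions of
√p: 0.4 for the four TC scores and 0.6 for the ten behavior variables
(larger bound = less penalization). Because 0.4·√4 < 1, the TC-side weight
vector of each of the K = 4 deflated pairs is exactly one ±1 coefficient;
pairs are re-signed so the TC coefficient is +1. The decomposition treats
within-set covariances as identity, so it coincides with classical CCA only
when within-set correlations vanish — the regime in which the whitened-SVD
CCA oracle is used as a cross-check.

**Mixed-effects slope.** `y ~ x` with mouse as random intercept, maximum
likelihood (REML optional); with a single group the model reduces to OLS.
The fixed-effect slope and its Wald p-value are reported.

## 4. Spiking cerebellar network

Two mirror-image groups (TC_Go, TC_Nogo), each a closed loop of 2000
granule cells (GrC), 100 Purkinje cells (PC), 100 cerebellar-nuclei
neurons (CN) and 100 inferior-olive neurons (IO) on a 10×10 lattice, plus
100 mossy-fiber (MF) and 100 error Poisson generators per group — 5,000
units in total. Leaky integrate-and-fire membranes
(τ_m = 10 ms; τ_ref = 5 ms, 50 ms for IO; V_th = −67 mV, −65 mV for IO;
V_reset = V_rest = −70 mV) with delta-current synapses, a 1-ms delay on
every connection and dt = 1 ms. Connections: MF→GrC random 5% (w = 10),
MF→CN full (10), GrC→PC full from both granule populations (same-group
weight plastic from 10, cross-group fixed at 10), PC→CN one-to-one (50,
inhibitory), Error→IO one-to-one (70), CN→IO one-to-one (inhibitory,
calibrated weight 70), IO→PC one-to-one (50), IO↔IO Gaussian lattice
(amplitude 10, σ = 2 lattice units, no self-connections), scaled by the
effective coupling gain g/g₀.

A trial is 500 ms. The presented cue selects which granule population is
recruited (the off-cue granule group is silent and relaxes to rest); CN
neurons carry a tonic depolarizing bias plus background membrane noise
giving ~26 Hz spontaneous rate, so the lick output never saturates. Per
trial:

    lick  = 6 − 6 / (1 + exp(−0.3 (CN_Go + CN_Nogo) + 16))      [Hz]
    error = 6 − lick   (Go)        error = −lick   (No-go)
    λ_Go  = −(4/3) error + 6       λ_Nogo = −(5/6) error + 2    [Hz, floor 0]

The error drive of trial t uses the lick rate of the *previous* trial of
the same cue (generator rates, like the coupling, are set before a trial
runs); the off-cue IO group receives a fixed 1.8-Hz baseline drive that
keeps its output near 1 Hz. The coefficient pair (4/3, 5/6) is the reading
of the error→IO maps consistent with the reported stage-wise IO rates; the
literal integer reading (43, 56) immediately clips to zero and is
selectable only for comparison.

End-of-trial updates, applied to the presented cue's group only (its
parallel fibers are the active ones and its IO carries the error signal):

    Δw_pf→pc = −α (IO − ĪO)    α = 0.01 (Go), 0.05 (No-go);
                               ĪO = 8 Hz (Go), 1 Hz (No-go); floor 0
    g_t      = g₀ − β (CN_{t−1, same cue} − CN₀)   β = 0.8 (Go), 0.5 (No-go);
                               g₀ = 5; floor 0

so IO below threshold potentiates (LTP) and above threshold depresses
(LTD). CN₀ and the initial lick estimate come from one unplastic warm-up
trial per cue. Cues are independent fair Bernoulli draws; the experiment is
500 trials × 10 seeded simulations, with stage statistics over the first
and last 100 trials and IO synchrony measured per own-cue trial as the mean
pairwise correlation of 10-ms-binned spike counts.

**Calibration constants.** The published connection tables fix sizes,
weights and delays but not the current-to-voltage scale of a spike. A
single global gain cannot work: a granule cell aggregates ~5 mossy inputs
while a Purkinje cell aggregates ~80,000 parallel-fiber events per second,
four orders of magnitude apart. One synaptic gain per postsynaptic
population is therefore calibrated (procedure scripted in
`scripts/calibrate_network.py`): k_GrC = 0.5 (mossy events suprathreshold,
GrC ≈ 19 Hz), k_PC = 1.5·10⁻³ (PC ≈ 75 Hz at the initial weight, the top
of the 40–80 Hz physiological band — the operating point at which the 2.5×
weight growth of learning produces the moderate CN changes the coupling
trajectory implies), k_CN = 0.0135 with bias 0.0695 mV/ms and membrane
noise 1.0 mV/√ms (CN ≈ 26.5 Hz; the noise stands in for unmodeled
background synaptic bombardment and linearizes the CN response to its
one-to-one PC inhibition — a noiseless near-threshold integrator responds
exponentially and would make the small stage-wise CN changes unreachable),
k_IO = 0.0857 (error events just suprathreshold; CN→IO weight 70 sets the
error-to-spike transmission), coupling gain 0.103 per unit template weight
(below the avalanche threshold of the lattice, so rates stay in the 0–10 Hz
band while synchrony grows with g).

**Known limitations.**

* After potentiation to w ≈ 25 the PC_Go rate reaches ~115 Hz, above the
  40–80 Hz band: no integrate-and-fire rate curve keeps a 2.5× drive
  increase inside the band while producing finite CN changes. Real Purkinje
  cells rely on short-term synaptic and intrinsic adaptation not modeled
  here.
* The error→IO maps, the plasticity rule and the reported stage-wise IO_Go
  rates are mutually inconsistent: a final Go weight of 25 under
  Δw = −0.01(IO − 8) over ~250 Go trials requires a mean IO_Go near 2 Hz,
  and the transmission that reproduces the No-go IO trajectory places
  IO_Go at ~1.5 Hz in the first stage. The simulation follows the printed
  equations, reproducing the lick, No-go IO, weight and coupling
  trajectories; its IO_Go rate runs below the reported 2.7→3.7 Hz.
* Lick timing within a trial, PC→CN convergence/divergence, and
  conductance-based membrane dynamics are intentionally not modeled.

## 5. Synthetic data

The generators provide every input the analyses need, with the statistical
structure the methods assume:

* **Behavior:** per-mouse hyperparameters from truncated normals anchored at
  the published per-mouse estimates (α 0.002±0.002, q₁ 0.12±0.07,
  q₂ 0.24±0.17, τ 0.14±0.07, ξ 0.84±0.24, truncated to the legal ranges);
  lick latencies HIT 0.25±0.15 s and FA 0.31±0.23 s (truncated at 0); HIT
  bouts sustained at ~4.4 Hz through the reward-delivery window, FA bouts
  dying out early, sporadic late licks (2–4 s) in all conditions.
* **Spikes:** inhomogeneous Poisson trains on a 10-ms grid over [−2, 2] s,
  intensity = 1 Hz baseline + planted 4-component CP structure
  (HIT-early, FA-early, HIT-reward-window and CR-selective components with
  zone-structured neuron loadings), scaled so the strongest planted
  response peaks 8 Hz above baseline. The per-trial gains of the first two
  components decrease linearly with the trial's δQ standardized *within*
  the component's expressed condition (HIT for the first, FA for the
  second), planting the negative within-condition couplings the
  association analyses should recover while preserving the condition
  selectivity itself; slopes are configuration knobs because the real-data
  magnitudes are not reproducible quantities.
* **Design fixtures:** standardized variables with known linear loadings
  into targets, for the PLS/sCCA oracle tests.

What passing tests on these data do *not* show: the generators contain no
calcium-indicator dynamics, imaging noise, slow drift, cross-neuron noise
correlations, or session-to-session nonstationarity, so recovery results
bound performance on ideal spike trains, not on raw imaging data.

## 6. Problem sizes and runtimes

Parameter recovery uses 20 replicates of 5,000 trials (~1 min); tensor
recovery uses 40 neurons × 50 bins × 4 conditions at signal-to-noise 5
across 10 seeds (~1 min); sparse-CCA sign recovery uses n = 2,000 across 20
seeds (~1 min); the network experiment is the full 500 trials × 10
simulations (~8 min). The analysis drivers under `analysis/` default to
reduced sizes (e.g. 3 network simulations) and state so in their output
files; `scripts/acceptance.py` always runs the full experiment.
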