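"""Seed-deterministic synthetic data with the structure the analyses assume.

Three generators:

* ``gen_behavior`` — mice whose lick choices follow the Q-learning generative
  model, hyperparameters drawn from truncated normals anchored at the
  per-mouse estimates (alpha 0.002+-0.002, q1 0.12+-0.07, q2 0.24+-0.17,
  tau 0.14+-0.07, xi 0.84+-0.24), lick latencies HIT 0.25+-0.15 s and
  FA 0.31+-0.23 s (truncated at 0), HIT lick bouts extending through the
  reward window at ~4.4 Hz.
* ``gen_spikes`` — complex-spike trains whose PSTH tensor carries a planted
  4-component non-negative CP structure over ~1 Hz Poisson baseline, with
  per-trial gains of the first two components tied (negatively) to the
  trial's reward-prediction error dQ.
* ``gen_design_fixture`` — standardized explanatory variables with known
  linear loadings into zone activity, for PLS/sCCA oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import qlearning as ql
from .io import ZONES
from .tca import CONDITIONS, PSTH_BIN, PSTH_WINDOW, TCAFactors

#: per-mouse hyperparameter anchors: (mean, sd), truncated to the legal ranges
PARAM_ANCHORS = {
    "alpha": (0.002, 0.002),
    "q1": (0.12, 0.07),
    "q2": (0.24, 0.17),
    "tau": (0.14, 0.07),
    "xi": (0.84, 0.24),
}

HIT_LATENCY = (0.25, 0.15)
FA_LATENCY = (0.31, 0.23)
HIT_LICK_RATE = 4.4  # Hz, sustained through the reward window
FA_LICK_RATE = 3.2
SPIKE_RESOLUTION = 0.01  # 10 ms spike-timing grid


@dataclass
class SynthConfig:
    n_mice: int = 4
    n_sessions: int = 7
    trials_per_session: int = 120
    p_go: float = 0.5
    baseline_rate: float = 1.0  # Hz
    snr: float = 5.0
    n_neurons_per_session: int = 12
    component_amplitude: float = 8.0  # peak planted rate above baseline, Hz
    dq_gain_slope: float = 0.8  # |slope| of the dQ -> TC1/TC2 gain coupling
    spike_span: tuple[float, float] = (-2.0, 2.0)


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    x = rng.normal(mean, sd, size)
    while np.any((x < lo) | (x > hi)):
        bad = (x < lo) | (x > hi)
        x = np.where(bad, rng.normal(mean, sd, size), x)
    return x


def sample_params(rng: np.random.Generator) -> ql.QLearnParams:
    vals = {
        k: float(_truncnorm(rng, m, s, *ql.PARAM_BOUNDS[k]))
        for k, (m, s) in PARAM_ANCHORS.items()
    }
    return ql.QLearnParams(**vals)


def _lick_times(rng, condition: str) -> tuple[np.ndarray, float]:
    """Lick times and response latency for one trial.

    HIT: a bout starting at a truncated-normal latency, sustained through the
    reward-delivery window.  FA: an early unrewarded bout that dies out.
    CR/MISS: no licks in the response window (latency NaN).  All conditions
    occasionally show stray late licks (2-4 s), as real mice do.
    """
    times = np.array([])
    latency = np.nan
    if condition in ("HIT", "FA"):
        mean, sd = HIT_LATENCY if condition == "HIT" else FA_LATENCY
        latency = float(_truncnorm(rng, mean, sd, 0.0, 4.0))
        if condition == "HIT":
            end = rng.uniform(1.8, 2.5)  # through reward delivery
            rate = HIT_LICK_RATE
        else:
            end = latency + rng.uniform(0.2, 0.8)
            rate = FA_LICK_RATE
        n = rng.poisson(max(end - latency, 0.0) * rate)
        times = np.concatenate([[latency], np.sort(rng.uniform(latency, end, n))])
    if rng.random() < 0.1:  # sporadic grooming/late licks
        times = np.concatenate([times, np.sort(rng.uniform(2.0, 4.0, rng.poisson(1.0) + 1))])
    return np.round(times, 4), latency


def gen_behavior(
    config: SynthConfig, seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, dict[str, ql.QTrace], dict[str, ql.QLearnParams]]:
    """Trial tables for ``n_mice`` mice with lick times and latencies.

    Returns (trials, per-mouse QTrace, per-mouse true parameters); trials are
    concatenated across sessions in chronological order per mouse.
    """
    rng = np.random.default_rng(seed)
    tables, traces, params = [], {}, {}
    for m in range(config.n_mice):
        mouse = f"mouse{m:02d}"
        p = sample_params(rng)
        n = config.n_sessions * config.trials_per_session
        cues = np.where(rng.random(n) < config.p_go, ql.GO, ql.NOGO)
        session = np.repeat(np.arange(config.n_sessions), config.trials_per_session)
        table, trace = ql.simulate_behavior(p, cues, rng, mouse=mouse, session=session)
        licks = [_lick_times(rng, c) for c in table["condition"]]
        table["lick_times"] = [t for t, _ in licks]
        table["lick_latency_s"] = [lat for _, lat in licks]
        tables.append(table)
        traces[mouse] = trace
        params[mouse] = p
    return pd.concat(tables, ignore_index=True), traces, params


# ---------------------------------------------------------------------------
# planted tensor structure
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def planted_factors(n_neurons: int, rng: np.random.Generator) -> TCAFactors:
    """Four components with condition-selective loadings and zone-structured
    neuron loadings, mirroring the reported component phenomenology:
    TC1 early/HIT, TC2 early/FA, TC3 reward-window/HIT, TC4 CR."""
    edges = np.arange(PSTH_WINDOW[0], PSTH_WINDOW[1] + PSTH_BIN / 2, PSTH_BIN)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def bump(mu, sd):
        return _unit(np.exp(-0.5 * ((centers - mu) / sd) ** 2))

    time = np.column_stack([bump(0.15, 0.1), bump(0.2, 0.12), bump(1.0, 0.4), bump(0.3, 0.2)])
    # condition loadings (HIT, FA, CR, MISS)
    cond = np.column_stack(
        [
            _unit(np.array([1.0, 0.15, 0.1, 0.05])),
            _unit(np.array([0.15, 1.0, 0.1, 0.05])),
            _unit(np.array([1.0, 0.3, 0.15, 0.05])),
            _unit(np.array([0.1, 0.2, 1.0, 0.05])),
        ]
    )
    # zone-structured neuron loadings: each component prefers a zone block
    zone_of = np.arange(n_neurons) % len(ZONES)
    prefs = [(2, 4), (1, 3), (4, 7), (1, 1)]  # zone index ranges per component
    neuron = np.zeros((n_neurons, 4))
    for r, (lo, hi) in enumerate(prefs):
        w = np.where((zone_of >= lo) & (zone_of <= hi), 1.0, 0.15)
        neuron[:, r] = _unit(w * rng.uniform(0.5, 1.5, n_neurons))
    lam = np.array([1.0, 0.9, 0.8, 0.7])
    return TCAFactors(
        lam=lam, neuron=neuron, time=time, condition=cond, bin_edges=edges,
        conditions=list(CONDITIONS),
    )


def gen_spikes(
    config: SynthConfig,
    trials: pd.DataFrame,
    qtrace_by_mouse: dict[str, ql.QTrace] | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, TCAFactors, pd.DataFrame]:
    """Inhomogeneous-Poisson spike tables with planted CP structure.

    Intensity of neuron n on trial j (condition c):
        baseline + gain_jr * A * sum_r lam_r w_nr b_r(t) a_cr
    where A sets the planted amplitude and gain_jr is 1 for TC3/TC4 and a
    decreasing linear function of the trial's standardized dQ for TC1/TC2
    (the negative coupling the association analyses should recover).
    Spike times are drawn on a 10-ms grid over ``config.spike_span``.

    Returns (spike table, ground-truth factors, per-trial gains).
    """
    rng = np.random.default_rng(seed)
    n_neurons = config.n_neurons_per_session
    mice = list(trials["mouse"].unique())
    factors = planted_factors(n_neurons * len(mice), rng)
    factors.neurons = np.array(
        [f"{m}_n{n:03d}" for m in mice for n in range(n_neurons)]
    )
    row_of = {nid: i for i, nid in enumerate(factors.neurons)}
    edges = factors.bin_edges
    centers = 0.5 * (edges[:-1] + edges[1:])

    # per-trial gains: dQ enters TC1/TC2 with negative slope, standardized
    # within the condition where each component is expressed (HIT for TC1,
    # FA for TC2) so the condition structure itself is preserved
    cond = trials["condition"].to_numpy()
    if qtrace_by_mouse is not None:
        dq = np.concatenate([qtrace_by_mouse[m].delta_q for m in trials["mouse"].unique()])
    else:
        dq = np.zeros(len(trials))

    def z_within(condition):
        """Standardized dQ on trials of ``condition``; zero elsewhere."""
        z = np.zeros(len(dq))
        sel = cond == condition
        if sel.sum() >= 2 and dq[sel].std() > 0:
            z[sel] = (dq[sel] - dq[sel].mean()) / dq[sel].std()
        return z

    s = config.dq_gain_slope
    gains = np.column_stack(
        [
            np.clip(1.0 - s * z_within("HIT"), 0.0, None),
            np.clip(1.0 - s * z_within("FA"), 0.0, None),
            np.ones(len(trials)),
            np.ones(len(trials)),
        ]
    )

    grid = np.arange(config.spike_span[0], config.spike_span[1], SPIKE_RESOLUTION)
    # planted rate profile per (component, grid point): b evaluated on the grid,
    # zero outside the PSTH window
    b_grid = np.zeros((4, len(grid)))
    inside = (grid >= PSTH_WINDOW[0]) & (grid < PSTH_WINDOW[1])
    idx = np.clip(np.searchsorted(edges, grid[inside], side="right") - 1, 0, len(centers) - 1)
    for r in range(4):
        b_grid[r, inside] = factors.time[idx, r]

    rows = []
    cond_index = {c: i for i, c in enumerate(CONDITIONS)}
    # scale so the largest planted intensity (gain 1) peaks at
    # ``component_amplitude`` Hz above baseline
    peak = 0.0
    for n in range(factors.neuron.shape[0]):
        for c in range(4):
            lam_nw = factors.lam * factors.neuron[n] * factors.condition[c]
            peak = max(peak, float((lam_nw @ b_grid).max()))
    amp = config.component_amplitude / peak
    trial_meta = trials.reset_index(drop=True)
    for j, rec in trial_meta.iterrows():
        c = cond_index[rec["condition"]]
        for n in range(n_neurons):
            nid = f"{rec['mouse']}_n{n:03d}"
            lam_nw = factors.lam * factors.neuron[row_of[nid]] * factors.condition[c]
            rate = config.baseline_rate + amp * (gains[j] * lam_nw) @ b_grid
            p = np.clip(rate * SPIKE_RESOLUTION, 0.0, 1.0)
            spikes = grid[rng.random(len(grid)) < p]
            rows.append(
                {
                    "neuron": nid,
                    "mouse": rec["mouse"],
                    "session": rec["session"],
                    "zone": ZONES[n % len(ZONES)],
                    "trial": rec["trial"],
                    "condition": rec["condition"],
                    "spike_times": np.round(spikes, 4),
                }
            )
    gains_df = pd.DataFrame(gains, columns=[f"gain_tc{r+1}" for r in range(4)])
    return pd.DataFrame(rows), factors, gains_df


def gen_design_fixture(
    n: int = 2000,
    seed: int | np.random.Generator = 0,
    loadings: np.ndarray | None = None,
    noise_sd: float = 1.0,
    n_vars: int = 10,
    n_targets: int = 8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardized design X and targets Y = X @ B + noise with known B."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, n_vars))
    x = (x - x.mean(0)) / x.std(0)
    if loadings is None:
        loadings = np.zeros((n_vars, n_targets))
    y = x @ loadings + noise_sd * rng.standard_normal((n, n_targets))
    return x, y, loadings
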