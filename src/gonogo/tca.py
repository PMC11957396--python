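"""PSTH tensors, non-negative tensor component analysis and trial TC scores.

Complex-spike trains are summarized as baseline-subtracted PSTHs over
[-0.5, 2] s (50-ms bins) for the four cue-response conditions, stacked into a
neurons x time x condition tensor.  The tensor is decomposed by non-negative
canonical polyadic (CP) factorization,

    x_ntk ~ sum_r  lambda_r * w_nr * b_tr * a_kr,

with each factor vector unit length and the scale absorbed into lambda_r.
The factors then act as a generative model for single trials: the activity of
neuron i on trial j (condition c) with respect to component r is the spike
train filtered by the component's temporal profile,

    y_ij^r = w_ir * a_cr * sum_s b_r(t_s),

and the session TC score of trial j is the mean of y over the session's
neurons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ZONES

CONDITIONS = ["HIT", "FA", "CR", "MISS"]

PSTH_WINDOW = (-0.5, 2.0)
PSTH_BIN = 0.05
BASELINE_WINDOW = (-2.0, -1.0)


@dataclass
class PSTHTensor:
    """Baseline-subtracted PSTHs (Hz), neurons x time bins x conditions."""

    values: np.ndarray
    bin_edges: np.ndarray
    conditions: list[str]
    neurons: np.ndarray  # neuron ids, row order of ``values``
    empty_mask: np.ndarray  # (n, k) True where a neuron had no trials


@dataclass
class TCAFactors:
    """Unit-length CP factors with scales ``lam``, sorted by lam descending."""

    lam: np.ndarray
    neuron: np.ndarray  # (n, R)
    time: np.ndarray  # (t, R)
    condition: np.ndarray  # (k, R)
    neurons: np.ndarray | None = None
    conditions: list[str] = field(default_factory=lambda: list(CONDITIONS))
    bin_edges: np.ndarray | None = None
    fit: float | None = None

    @property
    def rank(self) -> int:
        return len(self.lam)

    def reconstruct(self) -> np.ndarray:
        return np.einsum("r,nr,tr,kr->ntk", self.lam, self.neuron, self.time, self.condition)


def build_psth(
    spikes: pd.DataFrame,
    window: tuple[float, float] = PSTH_WINDOW,
    bin_width: float = PSTH_BIN,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    conditions: list[str] | None = None,
    min_trials: int = 1,
) -> PSTHTensor:
    """Per-neuron, per-condition PSTH tensor, baseline subtracted.

    ``spikes`` must carry columns neuron, trial, condition and spike_times
    (array-valued).  Rate per bin is count / (bin width x trial count), minus
    the neuron-condition mean rate in ``baseline_window``.  Conditions with
    fewer than ``min_trials`` trials for a neuron yield zero rows and are
    flagged in ``empty_mask`` (a near-empty average is dominated by single
    trials and can swamp a low-rank factorization).
    """
    if len(spikes) == 0:
        raise ValueError("empty spike table")
    conditions = conditions or CONDITIONS
    edges = np.arange(window[0], window[1] + bin_width / 2, bin_width)
    n_bins = len(edges) - 1
    neurons = np.array(sorted(spikes["neuron"].unique()))
    values = np.zeros((len(neurons), n_bins, len(conditions)))
    empty = np.zeros((len(neurons), len(conditions)), dtype=bool)
    base_dur = baseline_window[1] - baseline_window[0]

    for ni, (neuron, grp) in enumerate(spikes.groupby("neuron", sort=True)):
        for ki, cond in enumerate(conditions):
            sub = grp[grp["condition"] == cond]
            if len(sub) < max(min_trials, 1):
                empty[ni, ki] = True
                continue
            times = np.concatenate([np.atleast_1d(t) for t in sub["spike_times"]])
            counts, _ = np.histogram(times, bins=edges)
            n_base = np.sum((times >= baseline_window[0]) & (times < baseline_window[1]))
            baseline = n_base / (base_dur * len(sub))
            values[ni, :, ki] = counts / (bin_width * len(sub)) - baseline
    return PSTHTensor(values, edges, list(conditions), neurons, empty)


# ---------------------------------------------------------------------------
# non-negative CP by hierarchical alternating least squares
# ---------------------------------------------------------------------------


def _unfold(x: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(x, mode, 0).reshape(x.shape[mode], -1)


def _khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    r = a.shape[1]
    return (a[:, None, :] * b[None, :, :]).reshape(-1, r)


def _hals_sweep(x: np.ndarray, factors: list[np.ndarray]) -> None:
    for mode in range(3):
        others = [f for i, f in enumerate(factors) if i != mode]
        # khatri-rao in the order matching the unfolding's column layout
        kr = _khatri_rao(others[0], others[1])
        g = kr.T @ kr
        w = _unfold(x, mode) @ kr
        a = factors[mode]
        for r in range(a.shape[1]):
            denom = g[r, r]
            if denom < 1e-12:
                continue
            upd = a[:, r] + (w[:, r] - a @ g[:, r]) / denom
            np.maximum(upd, 0.0, out=upd)
            if not upd.any():  # rescue a dead component
                upd = np.full_like(upd, 1e-10)
            a[:, r] = upd


def ntf_decompose(
    tensor: np.ndarray | PSTHTensor,
    rank: int = 4,
    n_restarts: int = 10,
    seed: int | np.random.Generator = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> TCAFactors:
    """Non-negative CP decomposition, best of ``n_restarts`` random starts.

    Negative tensor entries (from baseline subtraction) are clipped at zero;
    the number of clipped entries is reported via a warning.  Factor vectors
    are normalized to unit length with the scale in lambda, and components are
    sorted by lambda descending.
    """
    meta: PSTHTensor | None = tensor if isinstance(tensor, PSTHTensor) else None
    x = np.asarray(tensor.values if meta is not None else tensor, dtype=float)
    if rank < 1:
        raise ValueError("rank must be >= 1")
    n_neg = int(np.sum(x < 0))
    if n_neg:
        warnings.warn(f"clipping {n_neg} negative tensor entries at 0 before NTF")
        x = np.clip(x, 0.0, None)
    norm_x = np.linalg.norm(x)
    if norm_x == 0:
        raise ValueError("all-zero tensor")

    rng = np.random.default_rng(seed)
    best_err, best_factors = np.inf, None
    for _ in range(n_restarts):
        factors = [rng.random((s, rank)) for s in x.shape]
        prev = np.inf
        for _ in range(max_iter):
            _hals_sweep(x, factors)
            err = np.linalg.norm(x - np.einsum("nr,tr,kr->ntk", *factors)) / norm_x
            if prev - err < tol:
                break
            prev = err
        if err < best_err:
            best_err, best_factors = err, [f.copy() for f in factors]

    lam = np.ones(rank)
    for f in best_factors:
        norms = np.linalg.norm(f, axis=0)
        norms[norms == 0] = 1.0
        f /= norms
        lam *= norms
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    best_factors = [f[:, order] for f in best_factors]
    return TCAFactors(
        lam=lam,
        neuron=best_factors[0],
        time=best_factors[1],
        condition=best_factors[2],
        neurons=meta.neurons if meta is not None else None,
        conditions=meta.conditions if meta is not None else list(CONDITIONS),
        bin_edges=meta.bin_edges if meta is not None else None,
        fit=1.0 - best_err,
    )


def congruence(f1: TCAFactors, f2: TCAFactors) -> np.ndarray:
    """Greedy per-component congruence (product of mode-wise cosines).

    Components of ``f1`` are matched to components of ``f2`` by greedy maximal
    cosine congruence; returns the matched scores in f1's component order.
    """

    def cos(a, b):
        na, nb = np.linalg.norm(a, axis=0), np.linalg.norm(b, axis=0)
        return (a / np.where(na == 0, 1, na)).T @ (b / np.where(nb == 0, 1, nb))

    c = cos(f1.neuron, f2.neuron) * cos(f1.time, f2.time) * cos(f1.condition, f2.condition)
    scores = np.full(f1.rank, np.nan)
    c = c.copy()
    for _ in range(min(f1.rank, f2.rank)):
        i, j = np.unravel_index(np.nanargmax(c), c.shape)
        scores[i] = c[i, j]
        c[i, :] = np.nan
        c[:, j] = np.nan
    return scores


# ---------------------------------------------------------------------------
# trial-wise component scores
# ---------------------------------------------------------------------------


def _temporal_profile_at(
    factors: TCAFactors, r: int, times: np.ndarray, interpolate: bool = False
) -> np.ndarray:
    edges = factors.bin_edges
    if edges is None:
        raise ValueError("factors carry no bin edges; decompose a PSTHTensor")
    b = factors.time[:, r]
    if interpolate:
        centers = 0.5 * (edges[:-1] + edges[1:])
        return np.interp(times, centers, b)
    idx = np.searchsorted(edges, times, side="right") - 1
    idx = np.clip(idx, 0, len(b) - 1)
    return b[idx]


def trial_tc_activity(
    spike_times: np.ndarray,
    factors: TCAFactors,
    neuron_index: int,
    condition: str,
    component: int,
    window: tuple[float, float] = PSTH_WINDOW,
    interpolate: bool = False,
) -> float:
    """y_ij^r: spike train filtered by the component's temporal profile.

    The temporal profile is evaluated piecewise-constant at each spike's
    50-ms bin (optionally linearly interpolated), scaled by the neuron and
    condition loadings.
    """
    if not 0 <= component < factors.rank:
        raise IndexError(f"component {component} out of range for rank {factors.rank}")
    t = np.asarray(spike_times, dtype=float)
    t = t[(t >= window[0]) & (t <= window[1])]
    if len(t) == 0:
        return 0.0
    k = factors.conditions.index(condition)
    b_at_spikes = _temporal_profile_at(factors, component, t, interpolate)
    return float(
        factors.neuron[neuron_index, component]
        * factors.condition[k, component]
        * np.sum(b_at_spikes)
    )


def session_tc_scores(
    spikes: pd.DataFrame,
    factors: TCAFactors,
    window: tuple[float, float] = PSTH_WINDOW,
    interpolate: bool = False,
) -> pd.DataFrame:
    """TC scores per trial: mean y over all neurons of each session.

    Returns one row per (mouse, session, trial) with columns tc1..tcR plus
    the trial's condition.
    """
    if factors.neurons is None:
        raise ValueError("factors carry no neuron ids")
    row_of = {nid: i for i, nid in enumerate(factors.neurons)}
    rows = []
    for (mouse, session, trial), grp in spikes.groupby(
        ["mouse", "session", "trial"], sort=True
    ):
        if len(grp) == 0:
            continue
        cond = grp["condition"].iloc[0]
        y = np.zeros(factors.rank)
        for _, rec in grp.iterrows():
            ni = row_of[rec["neuron"]]
            for r in range(factors.rank):
                y[r] += trial_tc_activity(
                    rec["spike_times"], factors, ni, cond, r, window, interpolate
                )
        y /= len(grp)
        rows.append(
            {"mouse": mouse, "session": session, "trial": trial, "condition": cond}
            | {f"tc{r + 1}": y[r] for r in range(factors.rank)}
        )
    return pd.DataFrame(rows)


def synchronized_spikes(
    spikes: pd.DataFrame, bin_width: float = 0.03, min_coactive: int = 2
) -> pd.DataFrame:
    """Keep only spikes co-active across neurons within 30-ms bins.

    A spike survives if its (session, trial, 30-ms bin) contains spikes from
    at least ``min_coactive`` distinct neurons.  Sessions with a single neuron
    produce empty trains (warned).
    """
    for (mouse, session), sess in spikes.groupby(["mouse", "session"], sort=False):
        n_neurons = sess["neuron"].nunique()
        if n_neurons < min_coactive:
            warnings.warn(
                f"session {mouse}/{session}: {n_neurons} neuron(s) < k={min_coactive}; "
                "all spikes dropped"
            )
    new_times: dict = {}
    for _, grp in spikes.groupby(["mouse", "session", "trial"], sort=False):
        binned = {
            idx: np.floor(np.atleast_1d(t) / bin_width).astype(int)
            for idx, t in grp["spike_times"].items()
        }
        counts: dict[int, set] = {}
        for idx, nid in grp["neuron"].items():
            for b in np.unique(binned[idx]):
                counts.setdefault(int(b), set()).add(nid)
        good = np.array(sorted(b for b, s in counts.items() if len(s) >= min_coactive))
        for idx, times in grp["spike_times"].items():
            bins = binned[idx]
            keep = np.isin(bins, good) if len(good) else np.zeros(len(bins), bool)
            new_times[idx] = np.atleast_1d(times)[keep]
    out = spikes.copy()
    out["spike_times"] = [new_times[i] for i in spikes.index]
    return out
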