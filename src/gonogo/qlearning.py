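"""Q-learning model of licking behavior in the Go/No-go auditory task.

Mice choose between Lick and No-lick after one of two auditory cues
(Go / No-go).  A state-action value Q(s, Lick) is learned from a
reward-penalty signal

    R-P = 1    for (Go, Lick)      -- HIT, rewarded
    R-P = -xi  for (No-go, Lick)   -- false alarm, punished by timeout
    R-P = 0    otherwise           -- CR and MISS

with the update

    dQ_t    = (R-P)_t - Q_t
    Q_{t+1} = Q_t + alpha * dQ_t

applied only to the realized (s, a) pair.  Q(s, No-lick) is fixed at 0
and never updated (for CR and MISS both Q and dQ are identically zero),
so the softmax policy compares Q(s, Lick) against 0:

    P(Lick | s) = exp(Q/tau) / (exp(Q/tau) + 1)

The five hyperparameters are the learning rate alpha, initial values
q1 = Q0(Go, Lick) and q2 = Q0(No-go, Lick), the softmax temperature tau
and the false-alarm penalty magnitude xi.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

GO, NOGO = "Go", "No-go"
LICK, NOLICK = "Lick", "No-lick"

#: printed legal ranges for the five hyperparameters
PARAM_BOUNDS = {
    "alpha": (0.001, 0.1),
    "q1": (0.0, 1.0),
    "q2": (0.0, 1.0),
    "tau": (0.01, 0.5),
    "xi": (0.0, 1.0),
}

PARAM_NAMES = tuple(PARAM_BOUNDS)


def condition_of(cue: str, action: str) -> str:
    """Deterministic cue-response condition label."""
    if cue == GO:
        return "HIT" if action == LICK else "MISS"
    if cue == NOGO:
        return "FA" if action == LICK else "CR"
    raise ValueError(f"unknown cue {cue!r}")


@dataclass(frozen=True)
class QLearnParams:
    """The five hyperparameters of the behavioral model."""

    alpha: float
    q1: float
    q2: float
    tau: float
    xi: float

    def __post_init__(self) -> None:
        for name, (lo, hi) in PARAM_BOUNDS.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.q1, self.q2, self.tau, self.xi])

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "QLearnParams":
        return cls(*map(float, x))


@dataclass
class QTrace:
    """Per-trial trajectories of the value model.

    ``q_go``/``q_nogo`` hold Q(s, Lick) *before* the trial's update, so
    the action probability of trial t is computed from them directly.
    ``delta_q`` and ``rp`` are zero on CR and MISS trials.
    """

    q_go: np.ndarray
    q_nogo: np.ndarray
    delta_q: np.ndarray
    rp: np.ndarray
    p_action: np.ndarray  # probability of the realized action


@dataclass
class FitResult:
    params: QLearnParams
    objective: float
    objective_mode: str
    n_trials: int
    h_go: np.ndarray
    f_go: np.ndarray
    h_nogo: np.ndarray
    f_nogo: np.ndarray
    r2_go: float
    r2_nogo: float
    bic: float | None
    log_likelihood: float | None
    unidentifiable: tuple[str, ...] = field(default_factory=tuple)


def reward_penalty(cue: str, action: str, xi: float) -> float:
    """R-P value of a trial: 1 for HIT, -xi for FA, 0 for CR/MISS."""
    if not 0.0 <= xi <= 1.0:
        raise ValueError("xi must lie in [0, 1]")
    cond = condition_of(cue, action)
    if cond == "HIT":
        return 1.0
    if cond == "FA":
        return -xi
    return 0.0


def q_update(q: float, rp: float, alpha: float) -> tuple[float, float]:
    """One value update: returns (delta_q, q_next)."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    dq = rp - q
    return dq, q + alpha * dq


def action_prob(q_lick: float | np.ndarray, tau: float) -> float | np.ndarray:
    """Softmax probability of Lick given Q(s, Lick), against Q(s, No-lick)=0."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    # P = e^{q/tau} / (e^{q/tau} + 1) = logistic(q / tau)
    x = np.asarray(q_lick, dtype=float) / tau
    p = np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x)))
    return float(p) if np.isscalar(q_lick) else p


def simulate_behavior(
    params: QLearnParams,
    cue_sequence: Sequence[str],
    rng: np.random.Generator | int,
    mouse: str = "m0",
    session: int | np.ndarray = 0,
) -> tuple[pd.DataFrame, QTrace]:
    """Sample actions from the model along a fixed cue sequence.

    Returns a trial table (without lick times; see synth.gen_behavior for
    fully dressed tables) and the value trace.
    """
    if len(cue_sequence) == 0:
        raise ValueError("cue_sequence is empty")
    rng = np.random.default_rng(rng)
    n = len(cue_sequence)
    session = np.broadcast_to(np.asarray(session), (n,))

    q = {GO: params.q1, NOGO: params.q2}
    rows = []
    trace = QTrace(*(np.zeros(n) for _ in range(5)))
    for t, cue in enumerate(cue_sequence):
        trace.q_go[t], trace.q_nogo[t] = q[GO], q[NOGO]
        p_lick = action_prob(q[cue], params.tau)
        lick = rng.random() < p_lick
        action = LICK if lick else NOLICK
        trace.p_action[t] = p_lick if lick else 1.0 - p_lick
        if lick:
            rp = reward_penalty(cue, action, params.xi)
            dq, q[cue] = q_update(q[cue], rp, params.alpha)
            trace.rp[t], trace.delta_q[t] = rp, dq
        rows.append(
            {
                "mouse": mouse,
                "session": int(session[t]),
                "trial": t,
                "cue": cue,
                "action": action,
                "condition": condition_of(cue, action),
            }
        )
    return pd.DataFrame(rows), trace


# ---------------------------------------------------------------------------
# likelihood machinery
#
# For a *fixed* observed trial sequence the Q trajectory is a closed form:
# Q(Go, Lick) changes only on HIT trials, each time by q <- q + a(1 - q),
# i.e. after m HITs  q = 1 - (1 - q1)(1 - a)^m ; similarly after m FAs
# q = -xi + (q2 + xi)(1 - a)^m.  This lets the objective be evaluated
# without a Python loop.
# ---------------------------------------------------------------------------


def _q_trajectories(
    trials: pd.DataFrame, alpha: float, q1: float, q2: float, xi: float
) -> tuple[np.ndarray, np.ndarray]:
    """Q(Go,Lick) and Q(No-go,Lick) *before* each trial's update."""
    is_hit = ((trials["cue"] == GO) & (trials["action"] == LICK)).to_numpy()
    is_fa = ((trials["cue"] == NOGO) & (trials["action"] == LICK)).to_numpy()
    n_hit_before = np.concatenate([[0], np.cumsum(is_hit)[:-1]])
    n_fa_before = np.concatenate([[0], np.cumsum(is_fa)[:-1]])
    decay = 1.0 - alpha
    q_go = 1.0 - (1.0 - q1) * decay**n_hit_before
    q_nogo = -xi + (q2 + xi) * decay**n_fa_before
    return q_go, q_nogo


class _LikelihoodData:
    """Cached arrays for fast repeated objective evaluation."""

    def __init__(self, trials: pd.DataFrame):
        self.is_go = (trials["cue"] == GO).to_numpy()
        self.licked = (trials["action"] == LICK).to_numpy()
        is_hit = self.is_go & self.licked
        is_fa = ~self.is_go & self.licked
        self.n_hit_before = np.concatenate([[0], np.cumsum(is_hit)[:-1]])
        self.n_fa_before = np.concatenate([[0], np.cumsum(is_fa)[:-1]])

    def prob(self, x: np.ndarray) -> np.ndarray:
        alpha, q1, q2, tau, xi = x
        decay = 1.0 - alpha
        q = np.where(
            self.is_go,
            1.0 - (1.0 - q1) * decay**self.n_hit_before,
            -xi + (q2 + xi) * decay**self.n_fa_before,
        )
        p_lick = action_prob(q, tau)
        return np.where(self.licked, p_lick, 1.0 - p_lick)


def trial_probabilities(trials: pd.DataFrame, params: QLearnParams) -> np.ndarray:
    """P(observed action | cue) for every trial under ``params``."""
    return _LikelihoodData(trials).prob(params.as_array())


def compute_qtrace(trials: pd.DataFrame, params: QLearnParams) -> QTrace:
    """Value/error trajectories implied by fitted parameters on observed data."""
    q_go, q_nogo = _q_trajectories(
        trials, params.alpha, params.q1, params.q2, params.xi
    )
    cue = trials["cue"].to_numpy()
    licked = (trials["action"] == LICK).to_numpy()
    q_realized = np.where(cue == GO, q_go, q_nogo)
    rp = np.where(licked, np.where(cue == GO, 1.0, -params.xi), 0.0)
    dq = np.where(licked, rp - q_realized, 0.0)
    p_lick = action_prob(q_realized, params.tau)
    return QTrace(
        q_go=q_go,
        q_nogo=q_nogo,
        delta_q=dq,
        rp=rp,
        p_action=np.where(licked, p_lick, 1.0 - p_lick),
    )


def _objective(x: np.ndarray, data: "_LikelihoodData", mode: str) -> float:
    p = data.prob(np.asarray(x))
    if mode == "sumprob":
        return -float(np.sum(p))
    return -float(np.sum(np.log(np.clip(p, 1e-300, None))))


def goodness_of_fit(h: Sequence[float], f: Sequence[float]) -> float:
    """Coefficient of determination R^2 = 1 - SSres/SStot between per-session
    data probabilities ``h`` and model probabilities ``f``.  May be negative.
    """
    h = np.asarray(h, dtype=float)
    f = np.asarray(f, dtype=float)
    if h.shape != f.shape:
        raise ValueError("h and f must have equal length")
    ss_tot = float(np.sum((h - h.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: data probabilities are constant across sessions")
    ss_res = float(np.sum((h - f) ** 2))
    return 1.0 - ss_res / ss_tot


def _session_fit_vectors(
    trials: pd.DataFrame, params: QLearnParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-session (h, f) for Go and No-go cues.

    h: fraction correct (Go) / fraction incorrect (No-go) per session.
    f: model P(Lick) at the session's last HIT (resp. FA) trial.  Sessions
    without a HIT (resp. FA) trial are dropped from that cue's vectors.
    """
    q_go, q_nogo = _q_trajectories(
        trials, params.alpha, params.q1, params.q2, params.xi
    )
    h_go, f_go, h_ng, f_ng = [], [], [], []
    idx = np.arange(len(trials))
    for _, sess in trials.assign(_i=idx).groupby("session", sort=True):
        go = sess[sess["cue"] == GO]
        ng = sess[sess["cue"] == NOGO]
        hits = go[go["action"] == LICK]
        fas = ng[ng["action"] == LICK]
        if len(go) and len(hits):
            h_go.append(len(hits) / len(go))
            f_go.append(action_prob(q_go[hits["_i"].iloc[-1]], params.tau))
        if len(ng) and len(fas):
            h_ng.append(len(fas) / len(ng))
            f_ng.append(action_prob(q_nogo[fas["_i"].iloc[-1]], params.tau))
    return (np.array(h_go), np.array(f_go), np.array(h_ng), np.array(f_ng))


def fit(
    trials: pd.DataFrame,
    objective_mode: Literal["sumprob", "loglik"] = "sumprob",
    n_starts: int = 10,
    seed: int | np.random.Generator = 0,
    bounds: dict[str, tuple[float, float]] | None = None,
    fixed: dict[str, float] | None = None,
    tie_q: bool = False,
) -> FitResult:
    """Fit the five hyperparameters to one animal's concatenated trials.

    Multi-start bounded L-BFGS-B (``n_starts`` seeded random starts plus the
    bound midpoint).  ``objective_mode`` selects the paper-literal sum of
    per-trial probabilities or the log-likelihood (required for BIC).
    ``fixed`` pins parameters (reduced models); ``tie_q`` shares q1 = q2.
    """
    if len(trials) == 0:
        raise ValueError("no trials to fit")
    if objective_mode not in ("sumprob", "loglik"):
        raise ValueError(f"unknown objective_mode {objective_mode!r}")
    bounds = dict(PARAM_BOUNDS, **(bounds or {}))
    fixed = dict(fixed or {})

    unidentifiable = []
    has_fa = bool(((trials["cue"] == NOGO) & (trials["action"] == LICK)).any())
    if not has_fa and "xi" not in fixed:
        # xi only enters through FA updates
        unidentifiable.append("xi")

    free = [p for p in PARAM_NAMES if p not in fixed and not (tie_q and p == "q2")]

    def expand(z: np.ndarray) -> np.ndarray:
        vals = dict(zip(free, z))
        vals.update(fixed)
        if tie_q and "q2" not in fixed:
            vals["q2"] = vals["q1"]
        return np.array([vals[p] for p in PARAM_NAMES])

    rng = np.random.default_rng(seed)
    lo = np.array([bounds[p][0] for p in free])
    hi = np.array([bounds[p][1] for p in free])
    starts = [0.5 * (lo + hi)] + [lo + rng.random(len(free)) * (hi - lo) for _ in range(n_starts)]

    data = _LikelihoodData(trials)
    best = None
    for x0 in starts:
        res = minimize(
            lambda z: _objective(expand(z), data, objective_mode),
            x0,
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
        )
        if best is None or res.fun < best.fun:
            best = res
    params = QLearnParams.from_array(expand(best.x))

    h_go, f_go, h_ng, f_ng = _session_fit_vectors(trials, params)

    def safe_r2(h, f):
        if len(h) < 2:
            return float("nan")
        try:
            return goodness_of_fit(h, f)
        except ValueError:
            return float("nan")

    loglik = -_objective(params.as_array(), data, "loglik")
    n_free = len(free)
    bic = (
        n_free * np.log(len(trials)) - 2.0 * loglik
        if objective_mode == "loglik"
        else None
    )
    return FitResult(
        params=params,
        objective=-best.fun,
        objective_mode=objective_mode,
        n_trials=len(trials),
        h_go=h_go,
        f_go=f_go,
        h_nogo=h_ng,
        f_nogo=f_ng,
        r2_go=safe_r2(h_go, f_go),
        r2_nogo=safe_r2(h_ng, f_ng),
        bic=bic,
        log_likelihood=loglik if objective_mode == "loglik" else loglik,
        unidentifiable=tuple(unidentifiable),
    )


#: default reduced-model ladder for information-criterion comparison: name ->
#: (fixed parameters, tie_q).  The full model is first; each reduction pins
#: parameters at neutral values (alpha always stays free).
DEFAULT_MODEL_LADDER: dict[str, tuple[dict[str, float], bool]] = {
    "full": ({}, False),
    "shared_q": ({}, True),
    "fixed_xi": ({"xi": 1.0}, False),
    "shared_q_fixed_xi": ({"xi": 1.0}, True),
    "value_free_only": ({"xi": 1.0, "q1": 0.5, "q2": 0.5, "tau": 0.14}, False),
}


def compare_models(
    trials: pd.DataFrame,
    ladder: dict[str, tuple[dict[str, float], bool]] | None = None,
    n_starts: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit every model of the ladder by maximum likelihood and rank by BIC."""
    ladder = ladder or DEFAULT_MODEL_LADDER
    rows = []
    for name, (fixed, tie_q) in ladder.items():
        r = fit(
            trials,
            objective_mode="loglik",
            n_starts=n_starts,
            seed=seed,
            fixed=fixed,
            tie_q=tie_q,
        )
        rows.append(
            {
                "model": name,
                "n_free": 5 - len(fixed) - int(tie_q),
                "log_likelihood": r.log_likelihood,
                "bic": r.bic,
                **asdict(r.params),
            }
        )
    return pd.DataFrame(rows).sort_values("bic").reset_index(drop=True)
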