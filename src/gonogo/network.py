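"""Spiking cerebellar network for modular reinforcement learning of Go/No-go.

Two mirror-image groups (TC_Go, TC_Nogo), each a closed PC-CN-IO loop:

* 2000 granule cells (GrC) per group, driven by 100 mossy fibers (MF,
  4-Hz Poisson) through random 5% connections; the presented cue selects
  which granule population is recruited on a trial.
* 100 Purkinje cells (PC) per group receiving all granule cells of both
  groups (parallel fibers); the same-group weight is plastic.
* 100 cerebellar-nuclei neurons (CN) per group, inhibited one-to-one by PCs,
  excited by MFs, with a tonic bias giving ~25 Hz spontaneous rate.
* 100 inferior-olive neurons (IO) per group on a 10x10 lattice with
  distance-decaying (Gaussian) coupling whose gain g is set trial-by-trial
  from CN activity, driven one-to-one by error Poisson generators and
  inhibited one-to-one by CN.

All neurons are leaky integrate-and-fire with delta-current synapses and a
1-ms delay; dt = 1 ms.  Per trial (500 ms):

    lick     = rate_max - rate_max / (1 + exp(-0.3 (CN_Go + CN_Nogo) + 16))
    error_Go = rate_max - lick          (Go trials)
    error_Ng = -lick                    (No-go trials)
    lam_Go   = -(4/3) error_Go + 6      (error input rate, Hz)
    lam_Ng   = -(5/6) error_Ng + 2
    dw       = -alpha (IO - IObar)      (same-group PF->PC weight, floor 0)
    g_t      = g0 - beta (CN_{t-1, same cue} - CN_0)   (floor 0)

The off-cue IO group receives a fixed baseline drive keeping it near 1 Hz.
Synaptic gains per postsynaptic population (and the CN bias, the CN->IO
weight and the baseline error rate, none of which are tabulated) are
calibration constants chosen by scripts/calibrate_network.py so that the
spontaneous rates sit in the physiological bands (PC 40-80 Hz, CN ~25 Hz,
IO 0-10 Hz) and the naive lick rate is ~3 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd

GO, NOGO = "Go", "No-go"
GROUPS = (GO, NOGO)


@dataclass(frozen=True)
class LIFParams:
    tau_m: float = 10.0  # ms
    tau_ref: float = 5.0  # ms
    v_th: float = -67.0  # mV
    v_reset: float = -70.0  # mV
    v_rest: float = -70.0  # mV

    def __post_init__(self):
        if not (self.v_reset <= self.v_rest < self.v_th):
            raise ValueError("need v_reset <= v_rest < v_th")


IO_LIF = LIFParams(tau_ref=50.0, v_th=-65.0)


@dataclass
class NetworkConfig:
    # population sizes (per group)
    n_grc: int = 2000
    n_pc: int = 100
    n_cn: int = 100
    io_side: int = 10  # 10x10 lattice
    n_mf: int = 100
    n_err: int = 100

    # Poisson drives
    mf_rate: float = 4.0  # Hz
    baseline_err_rate: float = 1.8  # Hz, off-cue IO drive (keeps IO ~1 Hz)

    # synaptic weights (connection table values)
    w_mf_grc: float = 10.0
    p_mf_grc: float = 0.05
    w_mf_cn: float = 10.0
    w_grc_pc: float = 10.0  # initial plastic same-group weight; also cross value
    w_pc_cn: float = 50.0
    w_err_io: float = 70.0
    w_io_pc: float = 50.0
    w_io_io: float = 10.0  # Gaussian template amplitude at g = g0
    w_cn_io: float = 70.0  # CN->IO one-to-one inhibition (calibrated)

    # per-population synaptic gains (mV per weight unit; calibrated)
    k_grc: float = 0.5
    k_pc: float = 1.5e-3
    k_cn: float = 0.0135
    k_io: float = 0.0857
    k_io_coupling: float = 0.103  # gain of the electrical-coupling kicks
    cn_bias: float = 0.0695  # mV/ms tonic depolarization of CN
    cn_noise_sd: float = 1.0  # mV/sqrt(ms) membrane noise (background drive)

    # lick / error maps
    rate_max: float = 6.0  # Hz
    sigmoid_slope: float = 0.3
    sigmoid_offset: float = 16.0
    err_coef: Literal["fractional", "literal"] = "fractional"

    # plasticity and coupling
    alpha_go: float = 0.01
    alpha_nogo: float = 0.05
    iobar_go: float = 8.0  # Hz
    iobar_nogo: float = 1.0
    beta_go: float = 0.8
    beta_nogo: float = 0.5
    g0: float = 5.0
    lattice_sigma: float = 2.0  # lattice units

    # integration
    dt: float = 1.0  # ms
    trial_ms: int = 500
    lif: LIFParams = field(default_factory=LIFParams)
    io_lif: LIFParams = field(default_factory=lambda: IO_LIF)


def lick_rate(cn_go_rate: float, cn_nogo_rate: float, cfg: NetworkConfig | None = None) -> float:
    """Sigmoid map from combined CN rates (Hz) to lick rate (Hz); decreasing."""
    cfg = cfg or NetworkConfig()
    if cn_go_rate < 0 or cn_nogo_rate < 0:
        raise ValueError("rates must be non-negative")
    x = -cfg.sigmoid_slope * (cn_go_rate + cn_nogo_rate) + cfg.sigmoid_offset
    return cfg.rate_max - cfg.rate_max / (1.0 + np.exp(x))


def compute_error(cue: str, lick: float, rate_max: float = 6.0) -> float:
    """Signed lick-rate error: rate_max - lick for Go (>=0), -lick for No-go."""
    if cue == GO:
        return rate_max - lick
    if cue == NOGO:
        return -lick
    raise ValueError(f"unknown cue {cue!r}")


def error_to_io_rate(error: float, cue: str, coef: str = "fractional") -> float:
    """Error -> Poisson rate of the cue's IO error input (Hz, clipped at 0).

    ``fractional`` reads the map coefficients as -4/3 and -5/6 (the reading
    consistent with the stage-wise IO rates); ``literal`` uses -43 and -56.
    """
    if coef == "fractional":
        c_go, c_ng = 4.0 / 3.0, 5.0 / 6.0
    elif coef == "literal":
        c_go, c_ng = 43.0, 56.0
    else:
        raise ValueError(f"unknown coef mode {coef!r}")
    lam = -c_go * error + 6.0 if cue == GO else -c_ng * error + 2.0
    return max(lam, 0.0)


def update_coupling(cn_prev: float, cn0: float, beta: float, g0: float) -> float:
    """Effective IO coupling for this trial from previous same-cue CN rate."""
    return max(g0 - beta * (cn_prev - cn0), 0.0)


def update_pfpc(weight: float, io_rate: float, alpha: float, iobar: float) -> float:
    """Bidirectional PF->PC weight update  w' = max(0, w - alpha (IO - IObar))."""
    return max(weight - alpha * (io_rate - iobar), 0.0)


def gaussian_lattice_weights(side: int, amplitude: float, sigma: float) -> np.ndarray:
    """Symmetric distance-decaying weights on a side x side lattice, no self."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    xy = np.stack(np.meshgrid(np.arange(side), np.arange(side), indexing="ij"), -1).reshape(-1, 2)
    d2 = np.sum((xy[:, None, :] - xy[None, :, :]) ** 2, axis=-1)
    w = amplitude * np.exp(-d2 / (2.0 * sigma**2))
    np.fill_diagonal(w, 0.0)
    return w


def poisson_drive(
    rate: float, duration_s: float, seed: int | np.random.Generator, dt_s: float = 0.001
) -> np.ndarray:
    """Homogeneous Poisson spike times over [0, duration); negative rates clip to 0."""
    rng = np.random.default_rng(seed)
    rate = max(rate, 0.0)
    n_steps = int(round(duration_s / dt_s))
    hits = rng.random(n_steps) < rate * dt_s
    return np.flatnonzero(hits) * dt_s


def synchrony_index(raster: np.ndarray, bin_steps: int = 10) -> float:
    """Mean pairwise correlation of binned spike counts, in [~0, 1].

    ``raster``: (n_neurons, n_steps) binary. Neurons with no spikes are
    excluded; fewer than two active neurons is an error.
    """
    raster = np.asarray(raster)
    active = raster.sum(axis=1) > 0
    if active.sum() < 2:
        raise ValueError("need at least two neurons with spikes")
    x = raster[active]
    n_bins = x.shape[1] // bin_steps
    binned = x[:, : n_bins * bin_steps].reshape(len(x), n_bins, bin_steps).sum(-1)
    c = np.corrcoef(binned)
    iu = np.triu_indices(len(binned), k=1)
    vals = c[iu]
    return float(np.nanmean(vals))


@dataclass
class TrialResult:
    trial: int
    cue: str
    lick: float
    error: float
    lam_err: float
    rates: dict  # population mean rates (Hz) per group
    w_pf: dict  # same-group GrC->PC weight after this trial's update
    g: dict  # coupling gain used this trial
    io_raster: dict | None = None  # (n_io, n_steps) binary per group


class _LIFPop:
    """Vectorized leaky integrate-and-fire population, delta synapses."""

    def __init__(self, n: int, p: LIFParams, dt: float, rng: np.random.Generator):
        self.p, self.dt, self.n = p, dt, n
        self.v = rng.uniform(p.v_reset, p.v_th, n)
        self.refr = np.zeros(n)
        self.spiked = np.zeros(n, dtype=bool)

    def step(self, input_mv: np.ndarray | float) -> np.ndarray:
        p, dt = self.p, self.dt
        ok = self.refr <= 0
        self.v[ok] += dt * (p.v_rest - self.v[ok]) / p.tau_m
        if np.isscalar(input_mv):
            self.v[ok] += input_mv
        else:
            self.v[ok] += input_mv[ok]
        self.refr[~ok] -= dt
        sp = ok & (self.v >= p.v_th)
        self.v[sp] = p.v_reset
        self.refr[sp] = p.tau_ref
        self.spiked = sp
        return sp


class CerebellarNetwork:
    """The two-group PC-CN-IO circuit with plasticity and coupling updates."""

    def __init__(self, config: NetworkConfig | None = None, seed: int | np.random.Generator = 0):
        self.cfg = cfg = config or NetworkConfig()
        self.rng = np.random.default_rng(seed)
        n_io = cfg.io_side**2
        self.pops = {}
        for grp in GROUPS:
            self.pops[grp] = {
                "grc": _LIFPop(cfg.n_grc, cfg.lif, cfg.dt, self.rng),
                "pc": _LIFPop(cfg.n_pc, cfg.lif, cfg.dt, self.rng),
                "cn": _LIFPop(cfg.n_cn, cfg.lif, cfg.dt, self.rng),
                "io": _LIFPop(n_io, cfg.io_lif, cfg.dt, self.rng),
            }
        # MF -> GrC random 5% (fixed per network instance)
        self.w_mfgrc = {
            grp: (self.rng.random((cfg.n_grc, cfg.n_mf)) < cfg.p_mf_grc).astype(float)
            * cfg.w_mf_grc
            for grp in GROUPS
        }
        # unit-amplitude lattice template; scaled by w_io_io * g / g0 each trial
        self.lattice = gaussian_lattice_weights(cfg.io_side, 1.0, cfg.lattice_sigma)
        self.w_pf = {GO: cfg.w_grc_pc, NOGO: cfg.w_grc_pc}
        self.w_cross = cfg.w_grc_pc
        self.g = {GO: cfg.g0, NOGO: cfg.g0}
        self.cn0 = {GO: None, NOGO: None}
        self.cn_prev = {GO: None, NOGO: None}
        self.lick_prev = {GO: None, NOGO: None}
        self.trial_count = 0
        self._warmed_up = False

    # -- single trial ------------------------------------------------------

    def _sim_trial(self, cue: str, lam_err: dict, record_raster: bool):
        """Simulate 500 ms; returns per-population rates and IO rasters."""
        cfg = self.cfg
        n_steps = int(round(cfg.trial_ms / cfg.dt))
        dt_s = cfg.dt / 1000.0
        other = {GO: NOGO, NOGO: GO}

        # pregenerate Poisson inputs (MF always at 4 Hz; error per group)
        mf = {g: self.rng.random((n_steps, cfg.n_mf)) < cfg.mf_rate * dt_s for g in GROUPS}
        err = {
            g: self.rng.random((n_steps, cfg.n_err)) < max(lam_err[g], 0.0) * dt_s
            for g in GROUPS
        }
        cn_noise = {
            g: cfg.cn_noise_sd * self.rng.standard_normal((n_steps, cfg.n_cn))
            for g in GROUPS
        }
        # the granule population of the non-presented cue receives no drive this
        # trial; reset it to rest (it has decayed there since its last trial)
        off_grp = {GO: NOGO, NOGO: GO}[cue]
        self.pops[off_grp]["grc"].v[:] = cfg.lif.v_rest
        self.pops[off_grp]["grc"].refr[:] = 0.0
        counts = {g: {k: 0.0 for k in ("grc", "pc", "cn", "io")} for g in GROUPS}
        rasters = (
            {g: np.zeros((cfg.io_side**2, n_steps), dtype=bool) for g in GROUPS}
            if record_raster
            else None
        )
        # previous-step spikes (1 ms delay)
        prev = {
            g: {
                "grc_count": 0.0,
                "pc": np.zeros(cfg.n_pc, bool),
                "cn": np.zeros(cfg.n_cn, bool),
                "io": np.zeros(cfg.io_side**2, bool),
                "mf_count": 0.0,
            }
            for g in GROUPS
        }
        w_io = {
            g: cfg.k_io_coupling * cfg.w_io_io * self.g[g] / cfg.g0 * self.lattice
            for g in GROUPS
        }
        no_grc = np.zeros(cfg.n_grc, bool)

        for t in range(n_steps):
            new = {}
            for g in GROUPS:
                pops = self.pops[g]
                # granule layer: recruited only on its cue's trials
                if g == cue:
                    cols = np.flatnonzero(mf[g][t])
                    i_grc = (
                        cfg.k_grc * self.w_mfgrc[g][:, cols].sum(axis=1)
                        if cols.size
                        else 0.0
                    )
                    sp_grc = pops["grc"].step(i_grc)
                else:
                    sp_grc = no_grc

                pf_same = self.w_pf[g] * prev[g]["grc_count"]
                pf_cross = self.w_cross * prev[other[g]]["grc_count"]
                i_pc = cfg.k_pc * (pf_same + pf_cross) + cfg.k_pc * cfg.w_io_pc * prev[g]["io"]
                sp_pc = pops["pc"].step(i_pc)

                i_cn = (
                    cfg.cn_bias * cfg.dt
                    + cfg.k_cn * cfg.w_mf_cn * prev[g]["mf_count"]
                    + cn_noise[g][t]
                    - cfg.k_cn * cfg.w_pc_cn * prev[g]["pc"]
                )
                sp_cn = pops["cn"].step(i_cn)

                i_io = cfg.k_io * (cfg.w_err_io * err[g][t] - cfg.w_cn_io * prev[g]["cn"]) + (
                    w_io[g] @ prev[g]["io"]
                )
                sp_io = pops["io"].step(i_io)

                counts[g]["grc"] += sp_grc.sum()
                counts[g]["pc"] += sp_pc.sum()
                counts[g]["cn"] += sp_cn.sum()
                counts[g]["io"] += sp_io.sum()
                if rasters is not None:
                    rasters[g][:, t] = sp_io
                new[g] = {
                    "grc_count": float(sp_grc.sum()),
                    "pc": sp_pc,
                    "cn": sp_cn,
                    "io": sp_io,
                    "mf_count": float(mf[g][t].sum()),
                }
            prev = new

        dur_s = n_steps * dt_s
        sizes = {"grc": cfg.n_grc, "pc": cfg.n_pc, "cn": cfg.n_cn, "io": cfg.io_side**2}
        rates = {
            g: {k: counts[g][k] / (sizes[k] * dur_s) for k in sizes} for g in GROUPS
        }
        return rates, rasters

    def warmup(self) -> None:
        """One unplastic trial per cue to set CN0 and the initial lick estimate."""
        for cue in GROUPS:
            lam = {cue: 0.0, ({GO: NOGO, NOGO: GO})[cue]: 0.0}
            lam[cue] = error_to_io_rate(
                compute_error(cue, self.cfg.rate_max / 2.0, self.cfg.rate_max),
                cue,
                self.cfg.err_coef,
            )
            lam[{GO: NOGO, NOGO: GO}[cue]] = self.cfg.baseline_err_rate
            rates, _ = self._sim_trial(cue, lam, record_raster=False)
            lick = lick_rate(rates[GO]["cn"], rates[NOGO]["cn"], self.cfg)
            self.cn0[cue] = rates[cue]["cn"]
            self.cn_prev[cue] = rates[cue]["cn"]
            self.lick_prev[cue] = lick
        self._warmed_up = True

    def run_trial(self, cue: str, record_raster: bool = False) -> TrialResult:
        if cue not in GROUPS:
            raise ValueError(f"unknown cue {cue!r}")
        if not self._warmed_up:
            self.warmup()
        cfg = self.cfg
        off = {GO: NOGO, NOGO: GO}[cue]

        # error drive from the previous same-cue trial's lick rate
        err_prev = compute_error(cue, self.lick_prev[cue], cfg.rate_max)
        lam = {
            cue: error_to_io_rate(err_prev, cue, cfg.err_coef),
            off: cfg.baseline_err_rate,
        }
        # coupling for this trial from previous same-cue CN rate
        beta = {GO: cfg.beta_go, NOGO: cfg.beta_nogo}[cue]
        self.g[cue] = update_coupling(self.cn_prev[cue], self.cn0[cue], beta, cfg.g0)

        rates, rasters = self._sim_trial(cue, lam, record_raster)
        lick = lick_rate(rates[GO]["cn"], rates[NOGO]["cn"], cfg)
        error = compute_error(cue, lick, cfg.rate_max)

        # end-of-trial plasticity on the presented cue's same-group PF weight
        alpha = {GO: cfg.alpha_go, NOGO: cfg.alpha_nogo}[cue]
        iobar = {GO: cfg.iobar_go, NOGO: cfg.iobar_nogo}[cue]
        self.w_pf[cue] = update_pfpc(self.w_pf[cue], rates[cue]["io"], alpha, iobar)

        self.cn_prev[cue] = rates[cue]["cn"]
        self.lick_prev[cue] = lick
        self.trial_count += 1
        return TrialResult(
            trial=self.trial_count - 1,
            cue=cue,
            lick=lick,
            error=error,
            lam_err=lam[cue],
            rates=rates,
            w_pf=dict(self.w_pf),
            g=dict(self.g),
            io_raster=rasters,
        )


@dataclass
class ExperimentSummary:
    trials: pd.DataFrame  # one row per (sim, trial)
    stage_summary: pd.DataFrame  # stage x cue means/sds across sims
    synchrony: pd.DataFrame  # per sim/stage/cue-group IO synchrony


def _stage_of(trial: int, n_trials: int, stage_len: int = 100) -> str | None:
    if trial < stage_len:
        return "first"
    if trial >= n_trials - stage_len:
        return "last"
    return None


def run_experiment(
    n_trials: int = 500,
    p_go: float = 0.5,
    n_sims: int = 10,
    seed: int = 0,
    config: NetworkConfig | None = None,
    record_synchrony: bool = True,
    synchrony_bin_steps: int = 10,
) -> ExperimentSummary:
    """Full learning experiment: ``n_sims`` seeded runs of ``n_trials`` trials.

    Cues are independent fair Bernoulli draws (probability ``p_go`` of Go).
    Stage statistics cover the first and last 100 trials.  IO synchrony is
    computed per own-cue trial in the first/last stages and averaged.
    """
    cfg = config or NetworkConfig()
    master = np.random.default_rng(seed)
    sim_seeds = master.integers(0, 2**31 - 1, size=n_sims)

    rows, sync_rows = [], []
    for s, sim_seed in enumerate(sim_seeds):
        rng = np.random.default_rng(sim_seed)
        net = CerebellarNetwork(cfg, rng)
        cues = np.where(rng.random(n_trials) < p_go, GO, NOGO)
        sync_acc: dict[tuple, list] = {}
        for t, cue in enumerate(cues):
            stage = _stage_of(t, n_trials)
            want_raster = record_synchrony and stage is not None
            res = net.run_trial(cue, record_raster=want_raster)
            rows.append(
                {
                    "sim": s,
                    "trial": t,
                    "cue": cue,
                    "lick": res.lick,
                    "error": res.error,
                    "lam_err": res.lam_err,
                    "io_go": res.rates[GO]["io"],
                    "io_nogo": res.rates[NOGO]["io"],
                    "cn_go": res.rates[GO]["cn"],
                    "cn_nogo": res.rates[NOGO]["cn"],
                    "pc_go": res.rates[GO]["pc"],
                    "pc_nogo": res.rates[NOGO]["pc"],
                    "grc_go": res.rates[GO]["grc"],
                    "grc_nogo": res.rates[NOGO]["grc"],
                    "w_go": res.w_pf[GO],
                    "w_nogo": res.w_pf[NOGO],
                    "g_go": res.g[GO],
                    "g_nogo": res.g[NOGO],
                }
            )
            if want_raster:
                try:
                    si = synchrony_index(res.io_raster[cue], synchrony_bin_steps)
                except ValueError:
                    si = np.nan
                sync_acc.setdefault((stage, cue), []).append(si)
        for (stage, cue), vals in sync_acc.items():
            sync_rows.append(
                {"sim": s, "stage": stage, "cue": cue, "synchrony": np.nanmean(vals)}
            )

    trials = pd.DataFrame(rows)
    trials["stage"] = [_stage_of(t, n_trials) for t in trials["trial"]]
    staged = trials.dropna(subset=["stage"])
    stage_summary = (
        staged.groupby(["stage", "cue"])
        .agg(
            lick_mean=("lick", "mean"),
            lick_sd=("lick", "std"),
            io_go_mean=("io_go", "mean"),
            io_nogo_mean=("io_nogo", "mean"),
            cn_go_mean=("cn_go", "mean"),
            cn_nogo_mean=("cn_nogo", "mean"),
            pc_go_mean=("pc_go", "mean"),
            pc_nogo_mean=("pc_nogo", "mean"),
        )
        .reset_index()
    )
    return ExperimentSummary(
        trials=trials,
        stage_summary=stage_summary,
        synchrony=pd.DataFrame(sync_rows),
    )
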