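"""Link trial-wise neural activity to reinforcement-learning variables.

Builds the ten explanatory variables (reward R, value Q, prediction error dQ,
six cue-crossed lick counts, latency fluctuation) from the synthetic cohort,
then runs the three association analyses:

* PLS regression with VIP scores of zone activity on the ten variables;
* sparse CCA between per-trial TC scores and the ten variables;
* mixed-effects slopes (mouse as random intercept) for the headline pairs.

Writes results/vip_scores.tsv, results/scca_coefficients.tsv and
results/mixed_slopes.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gonogo import qlearning as ql
from gonogo import regress, synth, tca

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = synth.SynthConfig(n_mice=3, n_sessions=4, trials_per_session=100,
                            n_neurons_per_session=16)
    trials, traces, _ = synth.gen_behavior(cfg, seed=SEED)
    spikes, truth, _ = synth.gen_spikes(cfg, trials, traces, seed=SEED + 1)

    # explanatory variables from the generative value traces
    designs = []
    for mouse, grp in trials.groupby("mouse", sort=False):
        d = regress.build_design(grp.reset_index(drop=True), traces[mouse])
        d[["mouse", "session", "trial"]] = grp[["mouse", "session", "trial"]].to_numpy()
        designs.append(d)
    design = pd.concat(designs, ignore_index=True)

    # zone activity: mean firing rate per zone in [-0.5, 2] s per trial
    zone_rows = []
    for (mouse, session, trial), grp in spikes.groupby(["mouse", "session", "trial"]):
        rates = {}
        for zone, zg in grp.groupby("zone"):
            n_spk = sum(((t >= -0.5) & (t <= 2.0)).sum() for t in zg["spike_times"])
            rates[zone] = n_spk / (2.5 * len(zg))
        zone_rows.append({"mouse": mouse, "session": session, "trial": trial, **rates})
    zones = pd.DataFrame(zone_rows).fillna(0.0)

    merged = design.merge(zones, on=["mouse", "session", "trial"])
    x = merged[regress.DESIGN_COLUMNS]
    zone_cols = [c for c in zones.columns if c not in ("mouse", "session", "trial")]

    vip_rows = []
    for zone in zone_cols:
        res = regress.pls_vip(x, merged[zone].to_numpy(), cv_folds=10, seed=SEED)
        vip_rows.append({"zone": zone, "n_components": res.n_components,
                         **dict(zip(regress.DESIGN_COLUMNS, res.vip))})
    vip = pd.DataFrame(vip_rows)
    vip.to_csv(OUT / "vip_scores.tsv", sep="\t", index=False)
    print("VIP scores by zone (variables > 1 are conventionally important):")
    print(vip.round(2).to_string(index=False))

    # trial TC scores from the recovered factors
    factors = tca.ntf_decompose(tca.build_psth(spikes), rank=4, n_restarts=6, seed=SEED)
    factors.neurons = np.array(sorted(spikes["neuron"].unique()))
    scores = tca.session_tc_scores(spikes, factors)
    sm = scores.merge(design, on=["mouse", "session", "trial"])
    res = regress.sparse_cca(sm[["tc1", "tc2", "tc3", "tc4"]], sm[regress.DESIGN_COLUMNS])
    coefs = pd.DataFrame(res.z_coefs, index=regress.DESIGN_COLUMNS,
                         columns=[f"pair{k+1}" for k in range(4)])
    coefs.loc["canonical_correlation"] = res.correlations
    coefs.to_csv(OUT / "scca_coefficients.tsv", sep="\t")
    print("\nsparse-CCA behavior-variable coefficients (TC side re-signed to +1):")
    print(coefs.round(2).to_string())

    slope_rows = []
    for tc_col, var in (("tc1", "Q"), ("tc1", "dQ"), ("tc2", "dQ"), ("tc3", "R")):
        slope, p = regress.mixed_model_slope(
            sm[tc_col].to_numpy(),
            regress.standardize(sm[[var]]).ravel(),
            sm["mouse"].to_numpy(),
        )
        slope_rows.append({"response": tc_col, "variable": var,
                           "slope": slope, "p": p})
    slopes = pd.DataFrame(slope_rows)
    slopes.to_csv(OUT / "mixed_slopes.tsv", sep="\t", index=False)
    print("\nmixed-effects slopes (mouse random intercept):")
    print(slopes.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
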