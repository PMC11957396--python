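"""Run the spiking cerebellar network through the Go/No-go learning task.

Three seeded simulations of 500 trials each (a reduced version of the
ten-simulation experiment that scripts/acceptance.py reproduces in full):
reports stage-wise lick rates, IO firing rates, the bidirectional weight
trajectories, the coupling endpoints and the IO synchrony contrast.

Writes results/network_trials.tsv, results/network_stage_summary.tsv and
results/network_synchrony.tsv.
"""

from pathlib import Path

from gonogo.network import run_experiment

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1
N_SIMS = 3  # the full experiment uses 10; 3 keeps this driver quick


def main() -> None:
    OUT.mkdir(exist_ok=True)
    summ = run_experiment(n_trials=500, p_go=0.5, n_sims=N_SIMS, seed=SEED,
                          record_synchrony=True)
    summ.trials.to_csv(OUT / "network_trials.tsv", sep="\t", index=False)
    summ.stage_summary.to_csv(OUT / "network_stage_summary.tsv", sep="\t", index=False)
    summ.synchrony.to_csv(OUT / "network_synchrony.tsv", sep="\t", index=False)

    g = summ.stage_summary.set_index(["stage", "cue"])
    tr = summ.trials
    print("stage-wise means over", N_SIMS, "simulations:")
    print(f"  lick Go     : {g.loc[('first','Go'),'lick_mean']:.2f} -> "
          f"{g.loc[('last','Go'),'lick_mean']:.2f} Hz")
    print(f"  lick No-go  : {g.loc[('first','No-go'),'lick_mean']:.2f} -> "
          f"{g.loc[('last','No-go'),'lick_mean']:.2f} Hz")
    print(f"  IO_Go  (Go trials)   : {g.loc[('first','Go'),'io_go_mean']:.2f} -> "
          f"{g.loc[('last','Go'),'io_go_mean']:.2f} Hz")
    print(f"  IO_Nogo(No-go trials): {g.loc[('first','No-go'),'io_nogo_mean']:.2f} -> "
          f"{g.loc[('last','No-go'),'io_nogo_mean']:.2f} Hz")
    final = tr.groupby("sim").tail(1)
    final_go = tr[tr.cue == "Go"].groupby("sim").tail(1)
    print(f"  PF->PC weight Go   : 10 -> {final['w_go'].mean():.1f}")
    print(f"  PF->PC weight No-go: 10 -> {final['w_nogo'].mean():.2f}")
    print(f"  coupling g (Go)    : 5 -> {final_go['g_go'].mean():.2f}")
    sync = summ.synchrony
    go_sync = sync[sync.cue == "Go"].groupby("stage")["synchrony"].mean()
    print(f"  IO_Go synchrony (Go trials): {go_sync['first']:.3f} -> {go_sync['last']:.3f}")


if __name__ == "__main__":
    main()
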