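"""Calibration procedure for the untabulated network constants.

The connection tables fix every synaptic weight and population size, but not
the current-to-voltage scale of a spike, the CN bias/noise, the CN->IO
inhibition weight, or the off-cue error-input rate.  This script documents
and reruns the procedure that produced the NetworkConfig defaults:

1. k_grc: mossy->granule events (w=10) made suprathreshold, so a granule
   cell relays its ~5 mossy inputs (~20 Hz drive -> ~19 Hz granule rate).
2. k_pc: with ~37 aggregated granule spikes/ms, place the Purkinje rate at
   the top of the physiological band (~75 Hz) at the initial weight 10 --
   the operating point at which the 2.5x weight increase of learning
   produces the moderate rate change the coupling trajectory implies.
3. cn_bias, k_cn, cn_noise_sd: put CN at ~26.5 Hz against ~75 Hz one-to-one
   PC inhibition (naive lick ~3 Hz through the printed sigmoid), with a
   disinhibition ceiling ~+5 Hz and an end-of-learning drop ~-3.5 Hz
   (the printed coupling endpoint g = 8 with beta = 0.8).
4. k_io, w_cn_io, baseline_err_rate, k_io_coupling: error events (w=70)
   suprathreshold, CN inhibition sized so the error->spike transmission
   matches the printed first-stage IO rate in No-go trials, baseline drive
   giving ~1 Hz off-cue IO firing, coupling gain below the avalanche
   threshold so rates stay in 0-10 Hz while synchrony grows with g.

Run:  python scripts/calibrate_network.py  (takes a few minutes; prints the
measured rates next to the bands they were calibrated to).
"""

import numpy as np

from gonogo.network import (
    GO,
    NOGO,
    CerebellarNetwork,
    NetworkConfig,
    lick_rate,
)


def main() -> None:
    cfg = NetworkConfig()
    net = CerebellarNetwork(cfg, seed=0)
    net.warmup()
    print("naive operating point (band / target in parentheses):")
    res = net.run_trial(GO)
    r = res.rates
    print(f"  GrC (cue)     {r[GO]['grc']:6.1f} Hz   (relay of ~20 Hz mossy drive)")
    print(f"  PC            {r[GO]['pc']:6.1f} Hz   (40-80)")
    print(f"  CN            {r[GO]['cn']:6.1f} Hz   (~25-27)")
    print(f"  IO off-cue    {r[NOGO]['io']:6.1f} Hz   (~1)")
    res = net.run_trial(NOGO)
    print(f"  IO No-go cue  {res.rates[NOGO]['io']:6.1f} Hz   (~2.5 at first-stage error)")
    lick = lick_rate(res.rates[GO]["cn"], res.rates[NOGO]["cn"], cfg)
    print(f"  naive lick    {lick:6.2f} Hz   (~3)")
    print("\nconfig defaults:")
    for k in ("k_grc", "k_pc", "k_cn", "k_io", "k_io_coupling", "cn_bias",
              "cn_noise_sd", "w_cn_io", "baseline_err_rate", "lattice_sigma"):
        print(f"  {k:18s} = {getattr(cfg, k)}")


if __name__ == "__main__":
    main()
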