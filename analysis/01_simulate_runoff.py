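#!/usr/bin/env python
"""Simulate harringtonine runoff time courses for each cell-type preset.

Generates, per preset, a 0/1/5/10/20-min time course of synthetic A254
polysome profiles (3 replicate seeds each) under scratch/sim/<preset>/
(bulky, fully regenerable intermediates) and the simulator's exact
ribosome-count fold-change series under results/sim/.  The traces are the
input for 02_quantify.
"""

from pathlib import Path

from runoffkit import runoff_kinetics as rk
from runoffkit import runoff_sim as sim
from runoffkit import trace_io

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "sim"
SERIES_OUT = ROOT / "results" / "sim"
TIMES = [0.0, 1.0, 5.0, 10.0, 20.0]
N_MRNAS = 4000
REPLICATE_SEEDS = (101, 102, 103)
PRESET_NAMES = ("hek", "hnsc", "rcn_immature", "rcn_mature")


def main() -> None:
    import dataclasses

    for name in PRESET_NAMES:
        out = OUT / name
        out.mkdir(parents=True, exist_ok=True)
        for rep, seed in enumerate(REPLICATE_SEEDS, start=1):
            config, pre = sim.preset(name, n_mrnas=N_MRNAS, seed=seed)
            truth, traces = sim.simulate_timecourse(config, TIMES,
                                                    pre_treatments=pre)
            for tr in traces:
                tr = dataclasses.replace(
                    tr, cell_type=name, replicate=str(rep),
                    sample_id=f"{name}_r{rep}_{tr.sample_id}",
                )
                trace_io.write_trace(tr, out / f"{tr.sample_id}.tsv")
            if rep == 1:
                SERIES_OUT.mkdir(parents=True, exist_ok=True)
                rk.write_series_tsv(
                    truth, SERIES_OUT / f"{name}_ground_truth.tsv"
                )
        print(f"{name}: wrote {len(TIMES) * len(REPLICATE_SEEDS)} traces "
              f"-> {out}")


if __name__ == "__main__":
    main()
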