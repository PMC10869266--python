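# runoffkit

Timed ribosome-runoff analysis for polysome profiling: quantify A254
sucrose-gradient traces, fit runoff decay kinetics to estimate ribosome
speed and the translationally inactive fraction, and reanalyse
fraction-resolved proteomics for polysome-to-monosome shifts.  A built-in
mechanistic runoff simulator supplies ground truth for every stage, so
the whole pipeline is testable without instrument data.

## The measurement and the model

Harringtonine (HRN) freezes initiating ribosomes at start codons while
elongating ribosomes run off their transcripts.  After a timed pulse
(stopped with cycloheximide, CHX), the polysome area of the gradient
profile — normalized to the t = 0 CHX control — declines as

    P(t) = C + (1 − C) · e^(−k t)

where the rate constant **k** (min⁻¹) tracks elongation speed and the
plateau **C** is the fraction of polysomal signal that never runs off:
translationally inactive ribosomes.  Neurons show a high plateau —
densely packed, puromycin-insensitive ribosome granules — while HEK-like
cells run off almost completely.  The package fits this model (and the
mirrored monosome rise M(t) = M∞ − (M∞ − 1)e^(−kt)), computes the
polysome/monosome ratio P/M, segments profiles with the fixed 8.9 mm
monosome-to-polysome offset from the 80S peak, and classifies proteomic
fraction shifts with vsn-style normalization, mixed MNAR/MAR imputation
and empirical-Bayes moderated t-tests (α = 0.05, |log2FC| > log2 1.5).

See `docs/methods.md` for the full model description, parameter tables
and design choices.

## Worked example

Simulate a mature-neuron runoff time course, quantify it and fit the
decay — either through the library or the CLI:

```bash
runoffkit run --preset rcn_mature --times 0,1,5,10 --seed 3 \
    --n-mrnas 800 --out rundir
# rcn_mature: k = 1.085 /min, plateau = 0.359, R^2 = 0.9998 -> rundir
```

The fitted plateau 0.36 recovers the preset's configured inactive
fraction (0.35): about a third of the polysomal signal survives a
10-minute runoff because it sits in inactive granules.  The same through
the library:

```python
import pandas as pd
from runoffkit import profile_quant as pq, runoff_kinetics as rk, runoff_sim as sim

config, pre = sim.preset("rcn_mature", n_mrnas=10_000, seed=3)
truth, traces = sim.simulate_timecourse(config, [0, 1, 2, 5, 10], pre_treatments=pre)

windows = sim.TraceConfig().search_windows()
quants = [pq.quantify_trace(t, windows) for t in traces]
meta = pd.DataFrame(
    {"sample_id": q.sample_id, "treatment": t.treatment,
     "runoff_time_min": t.runoff_time, "replicate": "1"}
    for q, t in zip(quants, traces)
)
fit = rk.fit_decay(rk.build_series(quants, meta, region="polysome"))
print(f"k = {fit.k:.2f}/min, plateau = {fit.plateau:.2f}")
```

The numbered drivers under `analysis/` run the full study-style
workflow (simulate presets → quantify → fit → compare; proteomics shift
reanalysis) and write their tables under `results/`.  Running
`analysis/03_fit_runoff_kinetics.py` on the simulated presets prints:

```
   condition  k_per_min  plateau  r_squared   pm0  rank
  rcn_mature      1.061    0.341      1.000 4.733     1
         hek      0.793    0.024      1.000 4.797     2
        hnsc      0.360    0.045      0.978 4.789     3
rcn_immature      0.277    0.078      0.970 4.779     4
```

— mature cortical neurons run off fastest *and* keep the highest
plateau, the signature of ribosome inactivation, while HEK cells combine
fast runoff with an almost complete decline.

For real data, `runoffkit quantify` reads two-column position/A254
TSV/CSV traces (with `# key: value` metadata headers or a sample-sheet
CSV), and `runoffkit proteomics-shift` reads a wide iBAQ TSV plus a
design CSV.

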