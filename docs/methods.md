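# Methods

## The timed ribosome-runoff measurement

Harringtonine (HRN) blocks the first peptide bond of initiating
ribosomes, pinning one 80S at each start codon while every ribosome that
is already elongating runs to the stop codon and dissociates.  Freezing
the reaction with cycloheximide (CHX) after a timed pulse and resolving
the lysate on a sucrose gradient therefore converts elongation speed into
a measurable decline of the polysome region of the A254 profile.  With
the polysome area at pulse length *t* expressed as a fold change of the
matched CHX (t = 0) control, the decline is modelled as first-order decay
with a plateau:

    P(t) = C + (1 − C) · e^(−k t)

* **k** (per minute) — the polysome rate constant, the proxy for
  elongation speed.  A ribosome at position *x* on a transcript of length
  *L* needs (L − x)/v seconds to leave, so for uniformly loaded
  transcripts the ensemble decline is approximately exponential with
  k ≈ 60·v/⟨L⟩; k is reported per minute because runoff pulses are
  minutes long.
* **C** (dimensionless, in [0, 1]) — the asymptote of the decline.  A
  nonzero plateau means part of the polysomal signal never runs off:
  translationally inactive ribosome–mRNA complexes.
* The intercept is pinned to 1 because the series is normalized to its
  own t = 0 control (`constrain_t0=True`, the default).  The functional
  form with a free intercept, C + A·e^(−kt), is available via
  `constrain_t0=False`; the measurement itself does not dictate which
  variant is correct, so both are implemented and the pinned form is the
  default on the argument above.

The monosome region rises as runoff products and HRN-stalled initiation
complexes accumulate; it is fitted with the mirrored form
M(t) = M∞ − (M∞ − 1)·e^(−kt), M∞ ≥ 1.  Puromycin-incorporation decay
series (nascent-chain labelling during runoff) use the same decline model
on pre-normalized signals.

### Fitting

Least squares on these models is non-convex in k.  For fixed k, however,
the model mean is affine in the plateau, so the fitter first scans a
dense log-spaced k grid (401 points in [0, 50]/min) with the plateau
profiled out in closed form (clipped to its bounds), then polishes the
grid winner with bounded trust-region least squares from three starts
(the winner and ×0.5/×2 perturbations).  On noiseless model points this
recovers parameters to better than 1e-6; on noisy series it matches an
exhaustive (k, C) grid search to 2e-3 (asserted in the test suite).
Plateau bounds are [0, 1]: fold changes cannot be negative, and the model
mean is not allowed to exceed the t = 0 anchor even when individual noisy
points do.  A series with zero spread returns k = 0 with a degenerate
flag rather than an error.  Replicates are fitted on their mean series
(replicate values are retained for dispersion checks).

Identifiability caveat: with observations only out to 10 min, a slow rate
(k ≈ 0.1/min) and a high plateau trade off strongly — the global optimum
itself scatters widely under σ = 0.02 noise.  This is a property of the
design, not the optimizer; recovery statistics are therefore quoted as
ensemble medians over the tested (k, C) grid.

## Profile quantification

* **Baseline**: default `linear_endpoints` — a line through the mean of
  the first and last 2 % of points, the simplest defensible model for a
  UV trace whose extremes are signal-free; `rolling_minimum` (rolling
  minimum, then a same-width moving average) is available for drifting
  baselines.  Corrected traces are clipped at zero.
* **Peaks**: most prominent local maximum per labelled search window
  (scipy `find_peaks`), centre refined by a 3-point parabolic fit.
  Missing required peaks raise a typed error naming the label.
* **Segmentation**: the polysome region starts a constant 8.9 mm
  downstream of the 80S peak centre — the fixed monosome-to-polysome
  distance used when analysing fractionator traces.  Whether that
  distance is centre-to-boundary or peak-to-peak is a convention choice;
  this package uses centre-to-boundary and exposes the offset
  (`mono_poly_offset`) for other fractionator geometries.  The monosome
  region runs from the 80S search-window start to that boundary;
  everything lighter is the subunit region (excluded from the monosome
  AUC, so 40S/60S shoulders never inflate P/M); everything beyond
  `gradient_end` (pellet) is excluded.
* **Integration**: trapezoid on the raw sampling grid with interpolated
  region boundaries — exact for the piecewise-linear interpolant, hence
  region areas are additive to machine precision; no smoothing, so no
  method-induced bias.  A zero monosome area yields P/M = NaN with a
  warning (never an exception) so batch runs survive degenerate inputs.
* **Dosing helper**: RNase1 units = 0.19 × A260 × lysate volume (μl),
  the dosing ratio used for controlled polysome digestion.

## The runoff simulator (synthetic-data generator)

The simulator provides mechanistic ground truth for every pipeline
stage.  Default study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_mrnas` | 2000 (10 000 in the headline plateau check) | mRNA population |
| length distribution | lognormal, ln-mean 6.0, ln-sd 0.45 (median ≈ 400 codons) | CDS lengths, typical mammalian transcriptome scale |
| `ribosome_spacing` | 60 codons | mean gap between loaded ribosomes (~1 per 180 nt) |
| `elongation_rate` | 5 codons/s | mammalian-range elongation speed |
| `exclusion_footprint` | 10 codons | minimum ribosome spacing |
| `f_inactive` | 0 | fraction of loaded mRNAs sequestered as granules |
| `free_80s_per_mrna` | 1.2 | free-monosome pool; also supplies HRN-stalled 80S |
| `noise_sd` | 0.002 A254 | detector noise on synthesized traces |

Loading draws Poisson(L/spacing) ribosomes per mRNA and places them
uniformly under the footprint constraint using the order-statistics
construction (n uniforms on [0, L−(n−1)g], sorted, shifted by i·g) —
distributionally identical to rejection sampling, without the loop.
Runoff of a single mRNA is deterministic given positions (transit-time
model, no per-codon stochasticity): the exponential-like ensemble decay
emerges from the length distribution.  TASEP-exact exclusion dynamics,
codon-specific dwell times and re-initiation are deliberately out of
scope.

Inactive granules are whole mRNA–ribosome complexes frozen in place —
the measurement cannot distinguish stalled from vacant dormant ribosomes,
so the simulator exposes only the single knob `f_inactive`.  In-silico
treatments: EDTA dissociates everything to subunits; puromycin releases
elongating ribosomes on active mRNAs (granules, and the nascent-chain-free
stalled start 80S, are insensitive); RNase1 collapses each active n-some
into n monosomes, destroys granule ribosomes (they leave no footprints),
and above the optimal dose destroys monosomes with probability
p_over = 1 − e^(−λ(units − u_opt)), λ = 0.5/u_opt by default — the
simplest monotone law that reproduces the observed drop of monosome yield
on over-digestion; NMDA stimulation relabels active loaded mRNAs to raise
the inactive fraction by `delta_f` (a no-op for the immature-neuron
preset).  Integer ribosome count is conserved exactly through every
operation except RNase digestion, which only destroys.

**Trace synthesis** renders a species census as unit-area Gaussians on a
0–60 mm gradient axis: 40S/60S at 13/17 mm, 80S at 23 mm, disome at
34 mm, higher n-somes compressing geometrically (spacing 4 mm, ratio
0.75, asymptote ≈ 50 mm — all peaks stay on the gradient so no signal is
clipped at the gradient end).  Species weight is proportional to RNA
content: n ribosomes + 0.3 mRNA-equivalents (an mRNA carries roughly a
third of a ribosome's RNA); free subunits count 0.5 each.  Granule signal
is spread as one wide Gaussian (43 ± 5 mm) across the polysome region —
detergent-dissolved granules enter the gradient rather than pelleting,
which is exactly why the inactive signal is measurable there.  A
high-resolution (5–25 %) geometry with resolved 80S/disome peaks is
provided for disome analyses.

**Cell-type presets** are illustrative parameter choices (no quantitative
per-cell-type inactive fractions or codon rates are published) fixed once
so that the qualitative biology holds: `hek` (5 codons/s, f = 0.03),
`hnsc` (2.5, 0.08), `rcn_immature` (1.8, 0.12), `rcn_mature` (6.0, 0.35 —
fastest runoff *and* the largest inactive pool), `rcn_mature_nmda`
(mature + NMDA Δf = 0.15).

What the generator does **not** emulate: transcript-specific runoff
heterogeneity, slowly elongating ribosome subpopulations, elongating
monosomes, baseline drift or fractionator artefacts beyond Gaussian
noise, and compositional differences between granule and polysome RNA.
Passing tests therefore demonstrate that the pipeline recovers the
parameters of this generative model — e.g. that the fitted plateau equals
the configured inactive fraction within ±0.1 at 10 000 mRNAs — not that
real traces are free of those complications.

## Fraction-resolved proteomics

Input: an iBAQ-scale intensity matrix (proteins × samples) over the
design {monosome, polysome} × {CHX, HRN} × replicates.

1. **Normalization** — per-sample median-ratio calibration (median log2
   ratio to the per-protein median reference), then the generalized log
   glog2(x) = log2((x + √(x² + c²))/2) with c set to the 5th percentile
   of calibrated observed intensities.  glog2 → log2 for x ≫ c, is
   strictly increasing (rank-preserving), and damps the variance blow-up
   near the detection limit.  Samples with fewer than 50 observed
   proteins are rejected.
2. **Mixed imputation** — MNAR if a protein is missing in *all*
   replicates of ≥ 1 condition (the simplest condition-wise reading of a
   mixed MNAR/MAR strategy): those gaps get the transformed-scale
   minimum.  Everything else is MAR: k-nearest-neighbour averaging over
   proteins (nan-Euclidean on co-observed entries, k = 10,
   deterministic).  All-missing proteins are dropped with a warning;
   nothing else is ever silently removed.
3. **Moderated tests** — per contrast, log2FC = mean_a − mean_b and a
   pooled residual variance s_g² with d_g = n_a + n_b − 2 df.  The
   empirical-Bayes prior (d0, s0²) is moment-matched on log variances:
   e_g = log s_g² − ψ(d_g/2) + log(d_g/2) has variance ψ′(d0/2) + ψ′(d_g/2)
   under the scaled-F hierarchy, so d0 comes from a trigamma inversion of
   the excess variance of e_g and s0² from its mean (closed form; d0 = ∞
   when variances are underdispersed).  The moderated statistic uses
   s̃² = (d0·s0² + d_g·s_g²)/(d0 + d_g) with d0 + d_g df; d0 → 0 recovers
   the classic equal-variance t, d0 → ∞ the fully pooled z-like
   statistic (both asserted in tests).
4. **Rejection and classification** — significant ⇔ adj_p < α and
   |log2FC| > lfc (defaults α = 0.05, lfc = log2 1.5).  Adjustment is
   Benjamini–Hochberg by default; because the adjustment variant behind
   published count-level results is often unstated, a Storey-style
   q-value mode (π0 from p > 0.5) is exposed behind `adjust="qvalue"`.
   The three shift sets: *polysome-enriched* (up in CHX polysome vs CHX
   monosome), *shifted-to-monosome* (its members down in HRN vs CHX
   polysomes — they leave with elongating ribosomes), and
   *HRN-polysome-elevated* (up in HRN vs CHX polysomes — retained on
   inactive ribosomes).  By construction the second is a subset of the
   first and disjoint from the third.

The proteomics generator plants these effects directly (per-protein log2
effects for polysome residency and runoff shifts), draws log-normal
intensities with per-sample scale factors (sd 0.15 log2) and within-group
sd 0.3 log2, and censors below an intensity quantile (MNAR) plus a random
MAR mask.  Additive background noise defaults to zero — label-free
matrices present their detection limit as censoring, not as an additive
floor — and is available as a parameter (the variance-flattening test
uses it).  The entry point is always the quantification matrix; raw
spectra processing is out of scope.

## Problem sizes and numerical choices

Headline checks run at the sizes stated with their results: 10 000 mRNAs
for plateau recovery and the closed-form runoff limit, 1 000 random
seeds (60 mRNAs each) for integer conservation, 100 random fixtures for
the quantification oracle, 100 seeded runs for the cell-type P/M
comparison, 200 Monte-Carlo replicates per (k, C) grid point for noisy
recovery, and 2 000-protein null / 1 000-protein planted simulations for
the statistics calibration.  Optimizer tolerances are 1e-15
(xtol/ftol/gtol) on the polish stage; integration boundary handling is
exact interpolation; ties in peak prominence resolve to the first
maximum; the trigamma inversion runs Newton to 1e-10 relative precision.

## Known limitations

* k_P is a per-population rate constant; converting it to codons/s needs
  transcript-length information that gradient profiles do not carry.
* Confidence intervals for (k, C) are not produced by profile
  likelihood; bootstrap over replicate series is the supported route.
* The 8.9 mm segmentation and the trace-synthesis geometry assume the
  standard fractionator; other instruments need the exposed offsets.
* The q-value mode uses a single-λ π0 estimate (λ = 0.5), adequate for
  the set sizes involved but cruder than spline-based estimators.
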