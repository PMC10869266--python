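"""Mechanistic stochastic simulator of harringtonine ribosome runoff.

The generator provides ground truth for every pipeline stage.  An mRNA
population with lognormal coding-sequence lengths is loaded with ribosomes
at steady state; a configurable fraction of loaded mRNAs is sequestered as
translationally inactive granules (frozen ribosome-mRNA complexes).  A
timed harringtonine (HRN) pulse lets every elongating ribosome on an
active mRNA run to the stop codon and leave, while one initiation-blocked
80S stays immobilized at the start codon; granules are untouched.  The
runoff of a single mRNA is deterministic given its ribosome positions
(transit-time model): the exponential-like ensemble decay emerges from the
length distribution, not from per-codon noise.

In-silico lysate treatments mirror the wet-lab controls: EDTA dissociates
every ribosome into subunits, puromycin (PMY) releases elongating
ribosomes but spares granules, RNase1 collapses active polysomes into
monosomes (destroying granule ribosomes, which leave no footprints) with
an over-digestion law at high doses, and NMDA stimulation raises the
inactive fraction in mature neurons.

A254 traces are synthesized from the species census as Gaussian peaks on a
gradient axis in mm, weighted by RNA content, so the full chain
simulate -> synthesize -> quantify -> fit can be checked against exact
internal ribosome counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParameterError
from .runoff_kinetics import RunoffSeries
from .trace_io import ProfileTrace

__all__ = [
    "SimConfig",
    "CellState",
    "SpeciesCounts",
    "TraceConfig",
    "init_steady_state",
    "apply_runoff",
    "apply_treatment",
    "census",
    "synthesize_trace",
    "simulate_timecourse",
    "simulate_proteomics",
    "ground_truth_pm",
    "PRESETS",
    "preset",
]

ACTIVE, INACTIVE = 0, 1


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of the runoff simulator.

    Lengths are in codons, speeds in codons/s, times at the interface in
    minutes.  ``ribosome_spacing`` is the mean codon gap between loaded
    ribosomes (so each mRNA carries ~Poisson(L/spacing) ribosomes);
    ``f_inactive`` is the fraction of ribosome-bearing mRNAs sequestered
    into inactive granules.  ``free_80s_per_mrna`` sizes the free-monosome
    pool that both shows up in the 80S peak and supplies the HRN-stalled
    start-codon ribosomes.
    """

    n_mrnas: int = 2000
    length_log_mean: float = 6.0   # ln codons; median ~403 codons
    length_log_sd: float = 0.45
    ribosome_spacing: float = 60.0
    elongation_rate: float = 5.0   # codons/s
    f_inactive: float = 0.0
    hrn_stall_at_start: bool = True
    exclusion_footprint: int = 10
    free_80s_per_mrna: float = 1.2
    free_subunit_pairs_per_mrna: float = 0.4
    noise_sd: float = 0.002        # A254 units added to synthesized traces
    seed: int = 0

    def __post_init__(self) -> None:
        if self.elongation_rate <= 0:
            raise ParameterError("elongation_rate must be > 0 codons/s")
        if self.ribosome_spacing < self.exclusion_footprint:
            raise ParameterError(
                f"ribosome_spacing ({self.ribosome_spacing}) must be >= "
                f"exclusion_footprint ({self.exclusion_footprint})"
            )
        if not 0.0 <= self.f_inactive <= 1.0:
            raise ParameterError("f_inactive must lie in [0, 1]")
        if self.n_mrnas < 1:
            raise ParameterError("n_mrnas must be >= 1")


@dataclass
class CellState:
    """Mechanistic state: ribosome positions on mRNAs plus free pools.

    Flat arrays keep the state vectorizable: ``ribo_pos[i]`` is the codon
    position of elongating ribosome i on mRNA ``ribo_mrna[i]``.  Start-
    stalled 80S (one per active mRNA under HRN) are tracked separately in
    ``stalled``.  ``destroyed`` counts ribosomes removed by RNase
    over-digestion (the one treatment allowed to break conservation, and
    only downward).
    """

    mrna_len: np.ndarray       # (n,) codons
    mrna_class: np.ndarray     # (n,) ACTIVE / INACTIVE
    stalled: np.ndarray        # (n,) bool, start-codon 80S present
    ribo_pos: np.ndarray       # (m,) codons
    ribo_mrna: np.ndarray      # (m,) mRNA index
    free_80s: int = 0
    free_subunits: int = 0
    destroyed: int = 0

    @property
    def n_mrnas(self) -> int:
        return self.mrna_len.size

    @property
    def total_ribosomes(self) -> int:
        """On-mRNA + stalled + free 80S + subunit pairs (conserved quantity)."""
        return int(
            self.ribo_pos.size
            + self.stalled.sum()
            + self.free_80s
            + self.free_subunits // 2
        )

    def copy(self) -> "CellState":
        return CellState(
            self.mrna_len.copy(), self.mrna_class.copy(), self.stalled.copy(),
            self.ribo_pos.copy(), self.ribo_mrna.copy(),
            self.free_80s, self.free_subunits, self.destroyed,
        )

    def ribosomes_per_mrna(self) -> np.ndarray:
        """Loaded ribosome count per mRNA (elongating + stalled)."""
        counts = np.bincount(self.ribo_mrna, minlength=self.n_mrnas)
        return counts + self.stalled.astype(int)


@dataclass
class SpeciesCounts:
    """Census of sedimenting species.

    ``nsomes[n]`` counts mRNAs carrying exactly n ribosomes (the 1-some
    bin also holds free 80S, which co-sediment with monosomes);
    ``granule_ribosomes``/``granule_mrnas`` cover the inactive pool.
    """

    nsomes: dict[int, int] = field(default_factory=dict)
    subunits: int = 0
    granule_ribosomes: int = 0
    granule_mrnas: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.nsomes.values()) or self.subunits < 0:
            raise ParameterError("species counts must be >= 0")

    @property
    def total_ribosomes(self) -> int:
        return int(
            sum(n * c for n, c in self.nsomes.items())
            + self.subunits // 2
            + self.granule_ribosomes
        )

    def polysome_ribosomes(self) -> int:
        """Ribosomes sedimenting in the polysome region (n >= 2 + granules)."""
        return (
            sum(n * c for n, c in self.nsomes.items() if n >= 2)
            + self.granule_ribosomes
        )

    def monosome_count(self) -> int:
        return self.nsomes.get(1, 0)


def _place_with_exclusion(n: int, length: int, gap: int, rng) -> np.ndarray:
    """Uniform positions on [0, L] with pairwise gaps >= gap.

    Order-statistics construction: draw n uniforms on [0, L - (n-1) gap],
    sort, then shift the i-th upward by i*gap.  Equivalent in distribution
    to rejection sampling the exclusion constraint, without the loop.
    """
    free = length - (n - 1) * gap
    u = np.sort(rng.random(n) * free)
    return u + gap * np.arange(n)


def init_steady_state(config: SimConfig, rng: np.random.Generator | None = None) -> CellState:
    """Draw the pre-HRN steady state for a cell population.

    Each mRNA gets Poisson(L/spacing) ribosomes (capped at the exclusion
    limit) placed uniformly with the footprint constraint; a fraction
    ``f_inactive`` of ribosome-bearing mRNAs is then relabelled as
    inactive granules.  Deterministic for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_mrnas
    lengths = np.maximum(
        rng.lognormal(config.length_log_mean, config.length_log_sd, n), 30.0
    ).astype(np.int64)
    counts = rng.poisson(lengths / config.ribosome_spacing)
    gap = config.exclusion_footprint
    counts = np.minimum(counts, lengths // gap + 1)

    pos_chunks, idx_chunks = [], []
    for i in range(n):
        c = int(counts[i])
        if c == 0:
            continue
        pos_chunks.append(_place_with_exclusion(c, int(lengths[i]), gap, rng))
        idx_chunks.append(np.full(c, i, dtype=np.int64))
    ribo_pos = (
        np.concatenate(pos_chunks) if pos_chunks else np.empty(0)
    )
    ribo_mrna = (
        np.concatenate(idx_chunks) if idx_chunks else np.empty(0, np.int64)
    )

    mrna_class = np.zeros(n, dtype=np.uint8)
    loaded = np.flatnonzero(counts > 0)
    n_inactive = int(round(config.f_inactive * loaded.size))
    if n_inactive > 0:
        chosen = rng.choice(loaded, size=n_inactive, replace=False)
        mrna_class[chosen] = INACTIVE

    return CellState(
        mrna_len=lengths,
        mrna_class=mrna_class,
        stalled=np.zeros(n, dtype=bool),
        ribo_pos=ribo_pos,
        ribo_mrna=ribo_mrna,
        free_80s=int(round(config.free_80s_per_mrna * n)),
        free_subunits=2 * int(round(config.free_subunit_pairs_per_mrna * n)),
    )


def apply_runoff(state: CellState, t: float, config: SimConfig) -> CellState:
    """Run off elongating ribosomes for a t-minute HRN pulse.

    A ribosome at codon x on an active mRNA of length L terminates iff its
    remaining transit time (L - x)/v fits in the pulse; it then joins the
    free 80S pool.  If ``hrn_stall_at_start``, every active mRNA retains
    one initiation-blocked 80S at codon 0 (drawn from the free pool).
    Inactive granules are untouched; t = 0 is the identity; the operation
    is idempotent once t exceeds the longest transit time.  Ribosome count
    is conserved exactly.
    """
    if t < 0:
        raise ParameterError("runoff time must be >= 0 minutes")
    new = state.copy()
    if t == 0:
        return new
    v = config.elongation_rate
    active_ribo = new.mrna_class[new.ribo_mrna] == ACTIVE
    remaining_s = (new.mrna_len[new.ribo_mrna] - new.ribo_pos) / v
    done = active_ribo & (remaining_s <= 60.0 * t)
    new.free_80s += int(done.sum())
    keep = ~done
    new.ribo_pos = new.ribo_pos[keep]
    new.ribo_mrna = new.ribo_mrna[keep]
    if config.hrn_stall_at_start:
        need = np.flatnonzero((new.mrna_class == ACTIVE) & ~new.stalled)
        n_stall = min(need.size, new.free_80s)
        new.stalled[need[:n_stall]] = True
        new.free_80s -= n_stall
    return new


def apply_treatment(
    state: CellState,
    treatment: str,
    rng: np.random.Generator | None = None,
    *,
    units: float | None = None,
    u_opt: float = 1.0,
    lam: float | None = None,
    delta_f: float = 0.0,
) -> CellState:
    """Apply an in-silico lysate/stimulation treatment.

    EDTA
        Dissociates every ribosome (on-mRNA, stalled, granule, free 80S)
        into free 40S/60S subunits.
    PMY
        Releases elongating ribosomes on active mRNAs to the free 80S
        pool.  Granules are PMY-insensitive and the initiation-blocked
        start-codon 80S carries no nascent chain, so both stay put.
    RNase1 (``units`` required)
        Converts each active n-some (stalled included) into n monosomes.
        Granule ribosomes are destroyed — they leave no footprints.  Above
        the optimal dose ``u_opt``, monosomes themselves are destroyed
        with probability p_over = 1 - exp(-lam * (units - u_opt)), the
        simplest monotone law reproducing the observed over-digestion
        (monosome yield drops again at high doses).  Default
        lam = 0.5 / u_opt.
    NMDA (``delta_f``)
        Relabels additional active loaded mRNAs as inactive granules to
        raise the inactive fraction by ``delta_f`` (mature neurons);
        delta_f = 0 is a no-op (immature neurons).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    new = state.copy()
    if treatment == "EDTA":
        total = new.ribo_pos.size + int(new.stalled.sum()) + new.free_80s
        new.free_subunits += 2 * total
        new.ribo_pos = np.empty(0)
        new.ribo_mrna = np.empty(0, np.int64)
        new.stalled[:] = False
        new.free_80s = 0
        return new
    if treatment == "PMY":
        on_active = new.mrna_class[new.ribo_mrna] == ACTIVE
        new.free_80s += int(on_active.sum())
        new.ribo_pos = new.ribo_pos[~on_active]
        new.ribo_mrna = new.ribo_mrna[~on_active]
        return new
    if treatment == "RNase1":
        if units is None or units < 0:
            raise ParameterError("RNase1 requires units >= 0")
        if lam is None:
            lam = 0.5 / u_opt
        on_active = new.mrna_class[new.ribo_mrna] == ACTIVE
        new.free_80s += int(on_active.sum())
        was_stalled = new.stalled & (new.mrna_class == ACTIVE)
        new.free_80s += int(was_stalled.sum())
        new.stalled[new.mrna_class == ACTIVE] = False
        new.destroyed += int((~on_active).sum())  # granule ribosomes
        gran_stalled = new.stalled & (new.mrna_class == INACTIVE)
        new.destroyed += int(gran_stalled.sum())
        new.stalled[:] = False
        new.ribo_pos = np.empty(0)
        new.ribo_mrna = np.empty(0, np.int64)
        p_over = 1.0 - np.exp(-lam * max(0.0, units - u_opt))
        if p_over > 0 and new.free_80s > 0:
            lost = int(rng.binomial(new.free_80s, p_over))
            new.free_80s -= lost
            new.destroyed += lost
        return new
    if treatment == "NMDA":
        loaded = new.ribosomes_per_mrna() > 0
        n_loaded = int(loaded.sum())
        if n_loaded == 0 or delta_f == 0:
            return new
        cur_inactive = int(((new.mrna_class == INACTIVE) & loaded).sum())
        f_now = cur_inactive / n_loaded
        if not 0.0 <= f_now + delta_f <= 1.0:
            raise ParameterError(
                f"NMDA delta_f={delta_f} pushes inactive fraction outside [0,1]"
            )
        target = int(round((f_now + delta_f) * n_loaded))
        extra = target - cur_inactive
        if extra > 0:
            candidates = np.flatnonzero(loaded & (new.mrna_class == ACTIVE))
            chosen = rng.choice(candidates, size=min(extra, candidates.size),
                                replace=False)
            new.mrna_class[chosen] = INACTIVE
        return new
    raise ParameterError(f"unknown treatment {treatment!r}")


def census(state: CellState) -> SpeciesCounts:
    """Count sedimenting species; conservation holds exactly by integers.

    The stalled start-codon 80S counts toward its mRNA's n-some size, and
    free 80S are pooled into the monosome (n = 1) bin since they
    co-sediment.
    """
    per_mrna = state.ribosomes_per_mrna()
    active = state.mrna_class == ACTIVE
    act_counts = per_mrna[active]
    act_counts = act_counts[act_counts > 0]
    ns: dict[int, int] = {}
    if act_counts.size:
        bc = np.bincount(act_counts)
        for n in np.flatnonzero(bc):
            ns[int(n)] = int(bc[n])
    ns[1] = ns.get(1, 0) + state.free_80s
    gran = ~active
    return SpeciesCounts(
        nsomes={n: c for n, c in ns.items() if c > 0},
        subunits=state.free_subunits,
        granule_ribosomes=int(per_mrna[gran].sum()),
        granule_mrnas=int((per_mrna[gran] > 0).sum()),
    )


@dataclass(frozen=True)
class TraceConfig:
    """Geometry of the synthesized A254 trace (positions in mm from top).

    Peak centres compress with n as on a real gradient:
    mu_n = mu_disome + d * (1 - rho**(n-2)) / (1 - rho) for n >= 2.
    Species weights are proportional to RNA content: n ribosomes plus one
    mRNA-equivalent (``mrna_weight`` ribosome units); free subunits carry
    0.5 each.  Granule signal is spread as one wide Gaussian across the
    polysome region — detergent-dissolved granules enter the gradient
    instead of pelleting.
    """

    start: float = 0.0
    end: float = 60.0
    step: float = 0.25
    mu_40s: float = 13.0
    mu_60s: float = 17.0
    mu_80s: float = 23.0
    mu_disome: float = 34.0
    poly_spacing: float = 4.0
    poly_compression: float = 0.75
    sigma_subunit: float = 1.1
    sigma_mono: float = 1.4
    sigma_poly_growth: float = 0.06
    mu_granule: float = 43.0
    sigma_granule: float = 5.0
    mrna_weight: float = 0.3
    baseline: float = 0.02
    amplitude: float = 1.0   # A254*mm per 1000 ribosome-equivalents

    def __post_init__(self) -> None:
        mus = [self.mu_40s, self.mu_60s, self.mu_80s, self.mu_disome]
        if any(b <= a for a, b in zip(mus, mus[1:])):
            raise ParameterError("peak centres must be strictly increasing")
        if not 0 < self.poly_compression < 1:
            raise ParameterError("poly_compression must lie in (0, 1)")

    def mu_n(self, n: int) -> float:
        """Centre of the n-some peak."""
        if n == 1:
            return self.mu_80s
        rho = self.poly_compression
        return self.mu_disome + self.poly_spacing * (1 - rho ** (n - 2)) / (1 - rho)

    def sigma_n(self, n: int) -> float:
        return self.sigma_mono + self.sigma_poly_growth * (n - 1)

    def grid(self) -> np.ndarray:
        return np.arange(self.start, self.end + self.step / 2, self.step)

    @staticmethod
    def highres() -> "TraceConfig":
        """5–25 % gradient: light species spread out, 80S/disome resolved."""
        return TraceConfig(
            mu_40s=10.0, mu_60s=16.0, mu_80s=24.0, mu_disome=36.0,
            poly_spacing=5.5, poly_compression=0.75,
            sigma_subunit=1.3, sigma_mono=1.5,
            mu_granule=48.0, sigma_granule=6.5,
        )

    def search_windows(self) -> dict[str, tuple[float, float]]:
        """Peak search windows matched to this geometry."""
        half2 = (self.mu_disome - self.mu_80s) / 2
        return {
            "40S": (self.mu_40s - 2.5, (self.mu_40s + self.mu_60s) / 2),
            "60S": ((self.mu_40s + self.mu_60s) / 2, (self.mu_60s + self.mu_80s) / 2),
            "80S": ((self.mu_60s + self.mu_80s) / 2, self.mu_80s + half2),
            "disome": (self.mu_80s + half2, (self.mu_disome + self.mu_n(3)) / 2),
        }


def _gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))


def _species_weights(counts: SpeciesCounts, cfg: TraceConfig):
    """(mu, sigma, RNA weight) per species, in ribosome-equivalents."""
    out = []
    for n, c in sorted(counts.nsomes.items()):
        w = c * (n + cfg.mrna_weight)
        out.append((cfg.mu_n(n), cfg.sigma_n(n), w))
    if counts.subunits:
        out.append((cfg.mu_40s, cfg.sigma_subunit, 0.5 * counts.subunits / 2))
        out.append((cfg.mu_60s, cfg.sigma_subunit, 0.5 * counts.subunits / 2))
    if counts.granule_ribosomes:
        w = counts.granule_ribosomes + cfg.mrna_weight * counts.granule_mrnas
        out.append((cfg.mu_granule, cfg.sigma_granule, w))
    return out


def synthesize_trace(
    counts: SpeciesCounts,
    trace_cfg: TraceConfig | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    **trace_fields,
) -> ProfileTrace:
    """Render a species census as an A254 absorbance trace.

    Each species contributes a unit-area Gaussian scaled by its RNA weight
    (so its analytic area equals ``amplitude * weight / 1000``); Gaussian
    detector noise and a flat baseline offset are added on top.  Metadata
    fields for the returned :class:`ProfileTrace` come via ``trace_fields``.
    """
    cfg = trace_cfg or TraceConfig()
    x = cfg.grid()
    y = np.full_like(x, cfg.baseline)
    scale = cfg.amplitude / 1000.0
    for mu, sigma, w in _species_weights(counts, cfg):
        y += scale * w * _gauss(x, mu, sigma)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        y = y + rng.normal(0.0, noise_sd, x.size)
    return ProfileTrace(positions=x, absorbance=y, **trace_fields)


def ground_truth_pm(
    counts: SpeciesCounts,
    cfg: TraceConfig | None = None,
    boundary: float | None = None,
) -> float:
    """RNA-weighted P/M implied by a census under a trace geometry.

    Species are assigned to regions by their peak centre relative to the
    monosome/polysome boundary (default: 80S centre + 8.9 mm); subunit
    peaks are excluded, matching the quantifier's subunit region.
    """
    from .profile_quant import MONO_POLY_OFFSET_MM

    cfg = cfg or TraceConfig()
    if boundary is None:
        boundary = cfg.mu_80s + MONO_POLY_OFFSET_MM
    mono = poly = 0.0
    for mu, _, w in _species_weights(counts, cfg):
        if mu <= cfg.mu_60s + 1e-9:   # subunit peaks
            continue
        if mu < boundary:
            mono += w
        else:
            poly += w
    return poly / mono if mono > 0 else float("nan")


def simulate_timecourse(
    config: SimConfig,
    times: list[float],
    pre_treatments: list[tuple[str, dict]] | None = None,
    lysate_treatment: tuple[str, dict] | None = None,
    trace_cfg: TraceConfig | None = None,
) -> tuple[RunoffSeries, list[ProfileTrace]]:
    """Simulate a full runoff time course and synthesize one trace per time.

    Returns the exact ribosome-count polysome fold-change series (the
    ground truth a perfect quantification would recover) together with the
    synthesized traces.  ``pre_treatments`` (e.g. NMDA) act on the steady
    state before HRN; ``lysate_treatment`` (e.g. EDTA/PMY/RNase1) acts on
    every post-runoff state.  Fully reproducible from ``config.seed``.
    """
    times = sorted(float(t) for t in times)
    if times[0] != 0:
        raise ParameterError("times must include 0 (the CHX control)")
    rng = np.random.default_rng(config.seed)
    state0 = init_steady_state(config, rng)
    for name, params in pre_treatments or []:
        state0 = apply_treatment(state0, name, rng, **params)

    traces, truth = [], []
    for t in times:
        st = apply_runoff(state0, t, config)
        if lysate_treatment is not None:
            name, params = lysate_treatment
            st = apply_treatment(st, name, rng, **params)
        cts = census(st)
        truth.append(cts.polysome_ribosomes())
        treatment = "CHX" if t == 0 else "HRN"
        if lysate_treatment is not None and t > 0:
            name = lysate_treatment[0]
            if name in {"EDTA", "PMY"}:
                treatment = f"HRN+{name}"
            elif name == "RNase1":
                treatment = "RNase1"
        traces.append(
            synthesize_trace(
                cts, trace_cfg, noise_sd=config.noise_sd, rng=rng,
                sample_id=f"t{t:g}", treatment=treatment, runoff_time=t,
            )
        )
    ref = truth[0] if truth[0] > 0 else 1
    series = RunoffSeries(
        times=np.array(times),
        values=np.array(truth, dtype=float) / ref,
        kind="polysome_decline",
        label="ground_truth",
    )
    return series, traces


# --------------------------------------------------------------------------
# Cell-type presets.  The study prints no per-cell-type inactive fractions
# or codon rates; these values are illustrative choices that reproduce the
# qualitative orderings (HEK fast with few inactive ribosomes, mature
# cortical neurons fastest with the largest inactive pool, immature neurons
# and stem cells slower), documented in docs/methods.md.
# --------------------------------------------------------------------------

PRESETS: dict[str, dict] = {
    "hek": dict(elongation_rate=5.0, f_inactive=0.03),
    "hnsc": dict(elongation_rate=2.5, f_inactive=0.08),
    "rcn_immature": dict(elongation_rate=1.8, f_inactive=0.12),
    "rcn_mature": dict(elongation_rate=6.0, f_inactive=0.35),
    "rcn_mature_nmda": dict(elongation_rate=6.0, f_inactive=0.35,
                            _nmda_delta_f=0.15),
}


def preset(name: str, **overrides) -> tuple[SimConfig, list[tuple[str, dict]]]:
    """Build (SimConfig, pre_treatments) for a named cell-type preset."""
    if name not in PRESETS:
        raise ParameterError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    params = dict(PRESETS[name])
    delta = params.pop("_nmda_delta_f", 0.0)
    params.update(overrides)
    cfg = SimConfig(**params)
    pre = [("NMDA", {"delta_f": delta})] if delta else []
    return cfg, pre


# --------------------------------------------------------------------------
# Synthetic fraction-resolved proteomics
# --------------------------------------------------------------------------

def simulate_proteomics(
    n_proteins: int = 2000,
    n_replicates: int = 3,
    planted_shifts: pd.DataFrame | None = None,
    mar_rate: float = 0.0,
    mnar_quantile: float = 0.0,
    within_sd: float = 0.3,
    sample_scale_sd: float = 0.15,
    additive_sd: float = 0.0,
    seed: int = 0,
):
    """Generate an iBAQ-style intensity matrix with planted fraction shifts.

    Design: fractions {monosome, polysome} x treatments {CHX, HRN} x
    ``n_replicates``.  Per protein, log2 intensity is
    base + scale_j + poly_enrichment * [polysome] + hrn_poly * [HRN & poly]
    + hrn_mono * [HRN & mono] + noise, exponentiated to the intensity
    scale.  ``planted_shifts`` is a DataFrame indexed by protein row with
    any of the columns ``poly_enrichment``, ``hrn_poly``, ``hrn_mono``
    (log2 effects); unlisted proteins are null.

    Missingness: values in the lowest ``mnar_quantile`` of the intensity
    distribution are censored (MNAR, the detection limit); a further
    ``mar_rate`` of entries is masked at random (MAR).  An optional
    additive background (``additive_sd``, intensity units) models
    low-intensity detector noise.  Ground truth is attached as ``.truth``.
    """
    from .fraction_proteomics import AbundanceTable

    rng = np.random.default_rng(seed)
    fractions, treatments = ("monosome", "polysome"), ("CHX", "HRN")
    design_rows, names = [], []
    for frac in fractions:
        for trt in treatments:
            for rep in range(1, n_replicates + 1):
                names.append(f"{frac}_{trt}_{rep}")
                design_rows.append(
                    {"sample": names[-1], "fraction": frac,
                     "treatment": trt, "replicate": rep}
                )
    design = pd.DataFrame(design_rows).set_index("sample")

    base = rng.normal(24.0, 2.5, n_proteins)
    scale = rng.normal(0.0, sample_scale_sd, len(names))
    eff = pd.DataFrame(
        0.0, index=range(n_proteins),
        columns=["poly_enrichment", "hrn_poly", "hrn_mono"],
    )
    if planted_shifts is not None:
        for col in planted_shifts.columns:
            if col not in eff.columns:
                raise ParameterError(f"unknown planted effect column {col!r}")
            eff.loc[planted_shifts.index, col] = planted_shifts[col].astype(float)

    log2x = np.empty((n_proteins, len(names)))
    for j, row in enumerate(design_rows):
        mu = base + scale[j]
        if row["fraction"] == "polysome":
            mu = mu + eff["poly_enrichment"].to_numpy()
            if row["treatment"] == "HRN":
                mu = mu + eff["hrn_poly"].to_numpy()
        elif row["treatment"] == "HRN":
            mu = mu + eff["hrn_mono"].to_numpy()
        log2x[:, j] = mu + rng.normal(0.0, within_sd, n_proteins)
    intens = np.exp2(log2x)
    if additive_sd > 0:
        intens = np.maximum(
            intens + rng.normal(0.0, additive_sd, intens.shape), 1e-6
        )

    if mnar_quantile > 0:
        thr = np.quantile(intens, mnar_quantile)
        intens = np.where(intens < thr, np.nan, intens)
    if mar_rate > 0:
        mask = rng.random(intens.shape) < mar_rate
        intens = np.where(mask, np.nan, intens)

    data = pd.DataFrame(
        intens, index=[f"P{i:05d}" for i in range(n_proteins)], columns=names
    )
    truth = eff.copy()
    truth.index = data.index
    return AbundanceTable(data=data, design=design, stage="raw", truth=truth)
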