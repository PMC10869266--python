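"""Fraction-resolved proteomics differential-abundance analysis.

Reanalysis pipeline for label-free iBAQ matrices from monosome and
polysome gradient fractions of CHX- versus HRN-treated cells:

1. variance-stabilizing normalization — per-sample median-ratio
   calibration followed by a generalized-log (glog2) transform, which
   behaves like log2 at high intensity and stays bounded near the
   detection limit;
2. mixed imputation — a protein missing in every replicate of at least
   one (fraction, treatment) condition is treated as censored below the
   detection limit (MNAR) and imputed at the transformed-scale minimum;
   all other gaps are missing-at-random (MAR) and filled by k-nearest-
   neighbour averaging over proteins;
3. empirical-Bayes moderated t-tests per contrast, with the variance
   prior (d0, s0^2) moment-matched on log residual variances and p-values
   on d0 + d_g degrees of freedom; Benjamini-Hochberg adjustment by
   default (a Storey-style q-value mode is available);
4. rejection at adj_p < alpha and |log2FC| > lfc (defaults 0.05 and
   log2 1.5), and classification of the polysome/monosome shift sets.

The pipeline is deterministic end-to-end given an input table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.impute import KNNImputer
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, FitError, NormalizationError, ParameterError

__all__ = [
    "AbundanceTable",
    "DiffResult",
    "ShiftClasses",
    "vsn_normalize",
    "impute_mixed",
    "moderated_test",
    "apply_rejections",
    "classify_fraction_shifts",
    "p_adjust",
    "run_shift_pipeline",
    "read_abundance_tsv",
    "read_design_csv",
    "DEFAULT_ALPHA",
    "DEFAULT_LFC",
]

DEFAULT_ALPHA = 0.05
DEFAULT_LFC = math.log2(1.5)

FRACTIONS = ("monosome", "polysome")
TREATMENTS = ("CHX", "HRN")

#: Contrast keys used by the shift classification.
CONTRAST_POLY_VS_MONO_CHX = "polysome_vs_monosome_CHX"
CONTRAST_HRN_VS_CHX_POLY = "HRN_vs_CHX_polysome"

_STAGES = ("raw", "normalized", "imputed")


@dataclass
class AbundanceTable:
    """Proteins x samples intensity matrix with its design table.

    ``design`` is indexed by sample name with columns ``fraction``
    (monosome/polysome), ``treatment`` (CHX/HRN) and ``replicate``.
    ``stage`` tracks the processing state; after imputation no entry is
    missing.  ``truth`` optionally carries planted ground-truth effects
    from the simulator.
    """

    data: pd.DataFrame = field(repr=False)
    design: pd.DataFrame = field(repr=False)
    stage: str = "raw"
    truth: pd.DataFrame | None = field(default=None, repr=False)
    imputation_class: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ParameterError(f"unknown stage {self.stage!r}")
        missing = set(self.data.columns) - set(self.design.index)
        if missing:
            raise DesignError(f"design lacks sample(s): {sorted(missing)}")
        for col in ("fraction", "treatment", "replicate"):
            if col not in self.design.columns:
                raise DesignError(f"design lacks column {col!r}")
        cell_sizes = (
            self.design.loc[list(self.data.columns)]
            .groupby(["fraction", "treatment"], observed=True)
            .size()
        )
        if (cell_sizes < 2).any():
            bad = cell_sizes[cell_sizes < 2].index.tolist()
            raise DesignError(
                f"need >= 2 replicates per (fraction, treatment), short: {bad}"
            )
        if self.stage == "imputed" and self.data.isna().any().any():
            raise ParameterError("imputed table still contains missing values")

    def samples_of(self, fraction: str, treatment: str) -> list[str]:
        d = self.design.loc[list(self.data.columns)]
        sel = (d["fraction"] == fraction) & (d["treatment"] == treatment)
        return list(d.index[sel])

    def conditions(self) -> list[tuple[str, str]]:
        d = self.design.loc[list(self.data.columns)]
        return sorted(
            set(zip(d["fraction"], d["treatment"]))
        )


@dataclass
class DiffResult:
    """Per-protein moderated-test outcome for one contrast.

    ``table`` columns: log2FC (group_a minus group_b), t (moderated), p,
    adj_p, significant.  ``significant`` is NaN until
    :func:`apply_rejections` sets it per adj_p < alpha AND |log2FC| > lfc.
    """

    table: pd.DataFrame = field(repr=False)
    contrast: str = ""
    alpha: float | None = None
    lfc: float | None = None
    prior_df: float = float("nan")
    prior_var: float = float("nan")

    def __post_init__(self) -> None:
        need = {"log2FC", "t", "p", "adj_p"}
        if not need <= set(self.table.columns):
            raise ParameterError(f"DiffResult table needs columns {need}")
        p, q = self.table["p"], self.table["adj_p"]
        if ((p < 0) | (p > 1)).any():
            raise ParameterError("p-values outside [0, 1]")
        if (q < p - 1e-12).any():
            raise ParameterError("adjusted p-values below raw p-values")

    @property
    def significant(self) -> pd.Series:
        return self.table["significant"]

    def n_significant(self) -> int:
        return int(self.table["significant"].fillna(False).sum())


@dataclass
class ShiftClasses:
    """The three fraction-shift protein sets.

    ``shifted_to_monosome`` (polysome-resident proteins that move to
    monosomes on runoff) is a subset of ``chx_polysome_enriched``;
    ``hrn_polysome_elevated`` (proteins retained/raised in polysomes after
    runoff) is disjoint from it by construction.
    """

    chx_polysome_enriched: frozenset[str]
    shifted_to_monosome: frozenset[str]
    hrn_polysome_elevated: frozenset[str]

    def __post_init__(self) -> None:
        if not self.shifted_to_monosome <= self.chx_polysome_enriched:
            raise ParameterError(
                "shifted_to_monosome must be a subset of chx_polysome_enriched"
            )
        if self.shifted_to_monosome & self.hrn_polysome_elevated:
            raise ParameterError(
                "shifted_to_monosome and hrn_polysome_elevated must be disjoint"
            )

    def sizes(self) -> dict[str, int]:
        return {
            "chx_polysome_enriched": len(self.chx_polysome_enriched),
            "shifted_to_monosome": len(self.shifted_to_monosome),
            "hrn_polysome_elevated": len(self.hrn_polysome_elevated),
        }


# --------------------------------------------------------------------------
# Normalization
# --------------------------------------------------------------------------

def vsn_normalize(
    table: AbundanceTable, min_observed: int = 50, glog_quantile: float = 0.05
) -> AbundanceTable:
    """Variance-stabilizing normalization onto a log2-comparable scale.

    Per-sample scale factors are the medians of log2 ratios to the
    per-protein median reference (robust to differential proteins); the
    calibrated intensities then pass through glog2(x) =
    log2((x + sqrt(x^2 + c^2)) / 2) with ``c`` set to the
    ``glog_quantile`` of all calibrated observed intensities.  glog2 is
    strictly increasing (rank-preserving within samples) and tends to
    log2(x) for x >> c while damping the variance blow-up of log2 near
    the detection limit.
    """
    if table.stage != "raw":
        raise ParameterError(f"vsn_normalize expects stage 'raw', got {table.stage!r}")
    X = table.data.to_numpy(dtype=float)
    if np.nanmin(X) <= 0:
        raise ParameterError("intensities must be > 0 where present")
    n_obs = (~np.isnan(X)).sum(axis=0)
    if (n_obs < min_observed).any():
        bad = [c for c, n in zip(table.data.columns, n_obs) if n < min_observed]
        raise NormalizationError(
            f"sample(s) with < {min_observed} observed proteins: {bad}"
        )
    logx = np.log2(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ref = np.nanmedian(logx, axis=1, keepdims=True)
        scale = np.nanmedian(logx - ref, axis=0)  # per-sample log2 factor
    cal = X / np.exp2(scale)[None, :]
    c = float(np.nanquantile(cal, glog_quantile))
    c = max(c, np.nanmin(cal) * 1e-6, 1e-12)
    out = np.log2((cal + np.sqrt(cal**2 + c**2)) / 2.0)
    return replace(
        table,
        data=pd.DataFrame(out, index=table.data.index, columns=table.data.columns),
        stage="normalized",
    )


# --------------------------------------------------------------------------
# Imputation
# --------------------------------------------------------------------------

def impute_mixed(table: AbundanceTable, k: int = 10) -> AbundanceTable:
    """Mixed MNAR/MAR imputation on the normalized scale.

    A protein is MNAR if it is missing in *all* replicates of at least one
    (fraction, treatment) condition — systematic absence, read as
    censoring below the detection limit — and its missing entries get the
    minimum of the transformed scale (the "zero" of the glog scale).  All
    other proteins are MAR and their gaps are filled by k-nearest-
    neighbour averaging over proteins (nan-Euclidean distance on
    co-observed entries, k = 10).  Proteins missing everywhere are dropped
    with a warning.  Fully deterministic; rows keep protein-id order.
    """
    if table.stage != "normalized":
        raise ParameterError(
            f"impute_mixed expects stage 'normalized', got {table.stage!r}"
        )
    data = table.data
    all_missing = data.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} protein(s) missing in every "
            "sample",
            RuntimeWarning,
            stacklevel=2,
        )
        data = data.loc[~all_missing]
    X = data.to_numpy(dtype=float)
    if not np.isnan(X).any():
        return replace(
            table, data=data, stage="imputed",
            imputation_class=pd.Series("none", index=data.index),
            truth=None if table.truth is None else table.truth.loc[data.index],
        )

    cond_cols = {
        cond: [data.columns.get_loc(s) for s in table.samples_of(*cond)]
        for cond in table.conditions()
    }
    missing = np.isnan(X)
    mnar = np.zeros(X.shape[0], dtype=bool)
    for cols in cond_cols.values():
        mnar |= missing[:, cols].all(axis=1)

    scale_min = float(np.nanmin(X))
    X[mnar & True, :] = np.where(missing[mnar], scale_min, X[mnar])

    if np.isnan(X).any():
        imputer = KNNImputer(n_neighbors=k, weights="uniform")
        X = imputer.fit_transform(X)
        if X.shape[0] != data.shape[0]:  # pragma: no cover - defensive
            raise FitError("imputer dropped rows unexpectedly")
    cls = pd.Series(np.where(mnar, "MNAR", "MAR"), index=data.index)
    cls[~missing.any(axis=1)] = "none"
    return replace(
        table,
        data=pd.DataFrame(X, index=data.index, columns=data.columns),
        stage="imputed",
        imputation_class=cls,
        truth=None if table.truth is None else table.truth.loc[data.index],
    )


# --------------------------------------------------------------------------
# Moderated testing
# --------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve polygamma(1, y) = x for y > 0 (Newton on 1/y asymptote)."""
    if x <= 0:
        return float("inf")
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y - dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match the scaled-F prior (d0, s0^2) on log residual variances.

    Under the hierarchical model, e_g = log s_g^2 - digamma(df/2) +
    log(df/2) has mean log s0^2 + digamma(d0/2) - log(d0/2) and variance
    trigamma(d0/2) + trigamma(df/2); matching the sample mean and variance
    of e_g gives closed-form estimates (infinite d0 when the variances are
    underdispersed relative to chi-square scatter).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return float("inf"), float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2))
    if e_var <= 0:
        return float("inf"), float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    if d0 > 1e7:  # numerically indistinguishable from a point-mass prior
        return float("inf"), float(np.exp(e_mean))
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0_2


def moderated_test(
    table: AbundanceTable,
    contrast: tuple[tuple[str, str], tuple[str, str]],
    adjust: str = "bh",
    prior_df: float | None = None,
) -> DiffResult:
    """Empirical-Bayes moderated t-test of group_a versus group_b.

    ``contrast`` gives the two groups as (fraction, treatment) pairs;
    log2FC is mean_a - mean_b on the normalized scale.  The per-protein
    residual variance s_g^2 (pooled over both groups, d_g = n_a + n_b - 2
    df) is shrunk toward the moment-matched prior:
    s~^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g), and the moderated t gets
    d0 + d_g degrees of freedom.  ``prior_df`` overrides the estimated d0
    (0 recovers the classic equal-variance t; inf gives the fully pooled
    z-like statistic).
    """
    if table.stage != "imputed":
        raise ParameterError(
            f"moderated_test expects stage 'imputed', got {table.stage!r}"
        )
    (fa, ta), (fb, tb) = contrast
    cols_a = table.samples_of(fa, ta)
    cols_b = table.samples_of(fb, tb)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise DesignError(
            f"both groups need >= 2 samples, got {len(cols_a)} and {len(cols_b)}"
        )
    A = table.data[cols_a].to_numpy(dtype=float)
    B = table.data[cols_b].to_numpy(dtype=float)
    na, nb = A.shape[1], B.shape[1]
    dg = na + nb - 2
    if dg <= 0:
        raise FitError("zero residual degrees of freedom")
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    ss = ((A - mean_a[:, None]) ** 2).sum(axis=1) + (
        (B - mean_b[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / dg
    fc = mean_a - mean_b

    if prior_df is None:
        d0, s0_2 = estimate_variance_prior(s2, dg)
    else:
        d0 = float(prior_df)
        _, s0_2 = estimate_variance_prior(s2, dg)
        if d0 == 0:
            s0_2 = 0.0
    if np.isinf(d0):
        s_tilde2 = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s_tilde2 = (d0 * s0_2 + dg * s2) / (d0 + dg)
        df_total = d0 + dg
    se = np.sqrt(s_tilde2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    adj = p_adjust(p, method=adjust)
    out = pd.DataFrame(
        {
            "log2FC": fc,
            "t": t,
            "p": p,
            "adj_p": adj,
            "significant": pd.Series(pd.NA, index=table.data.index,
                                     dtype="boolean").to_numpy(),
        },
        index=table.data.index,
    )
    label = f"{fa}_{ta}_vs_{fb}_{tb}"
    return DiffResult(table=out, contrast=label, prior_df=d0, prior_var=s0_2)


def p_adjust(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: BH step-up or Storey-style q-values.

    The q-value mode estimates the null proportion pi0 from p > 0.5 and
    rescales the BH adjustment; with pi0 = 1 it coincides with BH.
    """
    p = np.asarray(p, dtype=float)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "qvalue":
        pi0 = min(1.0, float(np.mean(p > 0.5)) / 0.5) if p.size else 1.0
        pi0 = max(pi0, 1.0 / max(p.size, 1))
        q = pi0 * multipletests(p, method="fdr_bh")[1]
        # keep the adj_p >= p contract of the result table
        return np.minimum(np.maximum(q, p), 1.0)
    raise ParameterError(f"unknown adjustment method {method!r}")


def apply_rejections(
    diff: DiffResult, alpha: float = DEFAULT_ALPHA, lfc: float = DEFAULT_LFC
) -> DiffResult:
    """Set the significance flag: adj_p < alpha AND |log2FC| > lfc."""
    if not 0 < alpha <= 1:
        raise ParameterError("alpha must lie in (0, 1]")
    if lfc < 0:
        raise ParameterError("lfc threshold must be >= 0")
    tab = diff.table.copy()
    tab["significant"] = (tab["adj_p"] < alpha) & (tab["log2FC"].abs() > lfc)
    return replace(diff, table=tab, alpha=alpha, lfc=lfc)


def classify_fraction_shifts(diffs: dict[str, DiffResult]) -> ShiftClasses:
    """Derive the three shift sets from the two rejection-flagged contrasts.

    * ``chx_polysome_enriched``: significantly up in polysome vs monosome
      under CHX — the steady-state polysome residents.
    * ``shifted_to_monosome``: members of that set significantly *down* in
      HRN polysomes vs CHX polysomes — they leave with elongating
      ribosomes.
    * ``hrn_polysome_elevated``: significantly up in HRN vs CHX polysomes
      — retained or recruited on inactive ribosomes.
    """
    for key in (CONTRAST_POLY_VS_MONO_CHX, CONTRAST_HRN_VS_CHX_POLY):
        if key not in diffs:
            raise DesignError(f"missing contrast {key!r}")
    c1, c2 = diffs[CONTRAST_POLY_VS_MONO_CHX], diffs[CONTRAST_HRN_VS_CHX_POLY]
    for c in (c1, c2):
        if c.alpha is None:
            raise ParameterError(
                f"contrast {c.contrast!r} lacks rejection flags; call "
                "apply_rejections first"
            )
    t1, t2 = c1.table, c2.table
    sig1 = t1["significant"].fillna(False).astype(bool)
    sig2 = t2["significant"].reindex(t1.index).fillna(False).astype(bool)
    fc2 = t2["log2FC"].reindex(t1.index)
    enriched = frozenset(t1.index[sig1 & (t1["log2FC"] > 0)])
    down2 = frozenset(t1.index[sig2 & (fc2 < 0)])
    up2 = frozenset(t1.index[sig2 & (fc2 > 0)])
    return ShiftClasses(
        chx_polysome_enriched=enriched,
        shifted_to_monosome=enriched & down2,
        hrn_polysome_elevated=up2,
    )


# --------------------------------------------------------------------------
# Convenience pipeline + I/O
# --------------------------------------------------------------------------

def run_shift_pipeline(
    table: AbundanceTable,
    alpha: float = DEFAULT_ALPHA,
    lfc: float = DEFAULT_LFC,
    adjust: str = "bh",
    knn_k: int = 10,
) -> dict:
    """vsn -> mixed imputation -> moderated tests -> rejections -> shift sets.

    Returns ``{"diffs": {contrast: DiffResult}, "shifts": ShiftClasses,
    "summary": dict}``.
    """
    norm = vsn_normalize(table) if table.stage == "raw" else table
    imp = impute_mixed(norm, k=knn_k) if norm.stage == "normalized" else norm
    contrasts = {
        CONTRAST_POLY_VS_MONO_CHX: (("polysome", "CHX"), ("monosome", "CHX")),
        CONTRAST_HRN_VS_CHX_POLY: (("polysome", "HRN"), ("polysome", "CHX")),
    }
    diffs = {
        key: apply_rejections(
            moderated_test(imp, groups, adjust=adjust), alpha=alpha, lfc=lfc
        )
        for key, groups in contrasts.items()
    }
    shifts = classify_fraction_shifts(diffs)
    summary = {
        "alpha": alpha,
        "lfc": lfc,
        "adjust": adjust,
        "n_proteins": int(imp.data.shape[0]),
        "n_significant": {k: d.n_significant() for k, d in diffs.items()},
        "set_sizes": shifts.sizes(),
    }
    return {"diffs": diffs, "shifts": shifts, "table": imp, "summary": summary}


def read_abundance_tsv(table_path, design_path) -> AbundanceTable:
    """Read a wide proteinGroups-style TSV (first column protein id) plus a
    design CSV with columns sample, fraction, treatment, replicate."""
    data = pd.read_csv(table_path, sep="\t", index_col=0)
    data = data.apply(pd.to_numeric, errors="coerce")
    design = read_design_csv(design_path)
    return AbundanceTable(data=data, design=design, stage="raw")


def read_design_csv(path) -> pd.DataFrame:
    design = pd.read_csv(path)
    if "sample" not in design.columns:
        raise DesignError("design CSV needs a 'sample' column")
    return design.set_index("sample")
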