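"""Exponential runoff kinetics.

During a timed harringtonine (HRN) pulse, initiating ribosomes are frozen
at start codons while elongating ribosomes run off their transcripts, so
the polysome signal declines and the monosome signal rises.  Normalizing
each region's AUC to the t = 0 cycloheximide (CHX) control gives a
fold-change series whose decline is well described by first-order decay
with a plateau:

    P(t) = C + (1 - C) * exp(-k t)

``k`` (per minute) is the polysome rate constant — the proxy for ribosome
elongation speed — and the plateau ``C`` is the fraction of polysomal
signal that never runs off, i.e. translationally inactive ribosomes.  The
intercept is pinned to 1 because the series is normalized to its own t = 0
control; an unconstrained three-parameter variant is available via
``constrain_t0=False``.  The monosome rise is fitted with the mirrored
form M(t) = M_inf - (M_inf - 1) exp(-k t).

Least-squares on these models is non-convex in ``k``, so fits first scan a
dense log-spaced rate grid with the plateau profiled out in closed form,
then polish the winner with bounded multi-start least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DesignError, FitError, ParameterError
from .profile_quant import QuantResult, fold_change

__all__ = [
    "RunoffSeries",
    "DecayFit",
    "fit_decay",
    "fit_rise",
    "build_series",
    "compare_conditions",
    "load_series_tsv",
    "write_series_tsv",
]

SERIES_KINDS = ("polysome_decline", "monosome_rise", "pmy_decline")

_T0_TOL = 1e-9


@dataclass
class RunoffSeries:
    """Fold-change time series relative to the t = 0 control.

    ``values[0]`` is 1 by construction.  ``replicate_values`` optionally
    keeps the per-replicate fold changes (replicates x times) from which
    ``values`` is the mean.
    """

    times: np.ndarray  # minutes, strictly increasing, starts at 0
    values: np.ndarray
    kind: str
    replicate_values: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ParameterError("times and values must be equal-length 1-D")
        if t[0] != 0:
            raise ParameterError("series must start at t = 0")
        if np.any(np.diff(t) <= 0):
            raise ParameterError("times must be strictly increasing")
        if abs(v[0] - 1.0) > _T0_TOL:
            raise ParameterError(
                f"values[0] must be 1 (normalized to its own control), got {v[0]}"
            )
        if np.any(v < 0):
            raise ParameterError("fold changes must be >= 0")
        if self.kind not in SERIES_KINDS:
            raise ParameterError(f"unknown series kind {self.kind!r}")
        self.times, self.values = t, v
        if self.replicate_values is not None:
            rv = np.atleast_2d(np.asarray(self.replicate_values, dtype=float))
            if rv.shape[1] != t.size:
                raise ParameterError("replicate_values shape mismatch")
            self.replicate_values = rv


@dataclass
class DecayFit:
    """Result of a runoff-model fit.

    ``plateau`` is C for declines and M_inf for rises; ``amplitude`` is the
    decaying component's weight (|1 - plateau| when the intercept is
    pinned).  ``r_squared`` compares against the mean model and can be
    negative for pathological fits.
    """

    k: float  # per minute
    plateau: float
    amplitude: float
    r_squared: float
    residuals: np.ndarray = field(repr=False)
    n_points: int = 0
    constrained_t0: bool = True
    degenerate: bool = False
    kind: str = "polysome_decline"
    label: str = ""

    def predict(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        if self.kind == "monosome_rise":
            return self.plateau - (self.plateau - 1.0) * np.exp(-self.k * t)
        return self.plateau + self.amplitude * np.exp(-self.k * t)

    def to_dict(self) -> dict:
        return {
            "k_per_min": self.k,
            "plateau": self.plateau,
            "amplitude": self.amplitude,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "constrained_t0": self.constrained_t0,
            "degenerate": self.degenerate,
            "kind": self.kind,
            "label": self.label,
        }


_K_MAX = 50.0  # per minute; far above any physiological runoff rate


def _multistart(residual_fn, x0_list, bounds):
    best = None
    for x0 in x0_list:
        sol = least_squares(
            residual_fn, x0, bounds=bounds, xtol=1e-15, ftol=1e-15, gtol=1e-15
        )
        if best is None or sol.cost < best.cost:
            best = sol
    return best


def _r_squared(values: np.ndarray, resid: np.ndarray) -> float:
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def _k_grid(n: int = 400) -> np.ndarray:
    return np.concatenate([[0.0], np.geomspace(1e-3, _K_MAX, n)])


def _profile_decay_start(t: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Best (k, C) on a dense log k-grid, C profiled out in closed form.

    For fixed k the constrained model mean e + C (1 - e) is affine in C,
    so the conditional optimum is a clipped one-dimensional projection.
    The winner seeds the bounded least-squares polish, making the
    multi-start robust to the non-convexity in k at negligible cost.
    """
    ks = _k_grid()
    E = np.exp(-np.outer(ks, t))           # (grid, n)
    B = 1.0 - E
    den = (B * B).sum(axis=1)
    num = ((v[None, :] - E) * B).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.clip(np.where(den > 0, num / den, 0.0), 0.0, 1.0)
    sse = ((E + C[:, None] * B - v[None, :]) ** 2).sum(axis=1)
    i = int(np.argmin(sse))
    return float(ks[i]), float(C[i])


def fit_decay(series: RunoffSeries, constrain_t0: bool = True) -> DecayFit:
    """Fit P(t) = C + (1 - C) exp(-k t) to a declining fold-change series.

    Bounded least squares over k in [0, 50]/min and C in [0, 1] (fold
    changes below zero are unphysical, and the model mean never exceeds 1
    even when individual data points do).  With ``constrain_t0=False`` the
    three-parameter form C + A exp(-k t) is fitted instead.
    """
    if series.kind not in {"polysome_decline", "pmy_decline"}:
        raise ParameterError(
            f"fit_decay expects a declining series, got kind {series.kind!r}"
        )
    t, v = series.times, series.values
    if t.size < 3:
        raise FitError(f"need >= 3 time points, got {t.size}")
    if np.ptp(v) == 0:
        return DecayFit(
            k=0.0, plateau=float(v[0]), amplitude=0.0, r_squared=1.0,
            residuals=np.zeros_like(v), n_points=t.size,
            constrained_t0=constrain_t0, degenerate=True, kind=series.kind,
            label=series.label,
        )

    if constrain_t0:
        def resid(x):
            k, c = x
            return c + (1 - c) * np.exp(-k * t) - v

        k0, c0 = _profile_decay_start(t, v)
        starts = [(k0, c0), (max(k0 * 0.5, 1e-3), c0), (k0 * 2 + 1e-3, c0)]
        sol = _multistart(resid, starts, ([0.0, 0.0], [_K_MAX, 1.0]))
        k, c = sol.x
        amp = 1.0 - c
    else:
        def resid(x):
            k, c, a = x
            return c + a * np.exp(-k * t) - v

        k0, c0 = _profile_decay_start(t, v)
        a0 = float(v[0] - c0)
        starts = [(max(k0, 1e-3) * f, c0, a0) for f in (0.25, 1.0, 4.0)]
        sol = _multistart(
            resid, starts, ([0.0, 0.0, -10.0], [_K_MAX, 10.0, 10.0])
        )
        k, c, amp = sol.x
    r = sol.fun
    return DecayFit(
        k=float(k), plateau=float(c), amplitude=float(amp),
        r_squared=_r_squared(v, r), residuals=r, n_points=t.size,
        constrained_t0=constrain_t0, kind=series.kind, label=series.label,
    )


def fit_rise(series: RunoffSeries) -> DecayFit:
    """Fit the monosome rise M(t) = M_inf - (M_inf - 1) exp(-k t).

    ``plateau`` stores M_inf >= 1, the asymptotic monosome fold change.
    """
    if series.kind != "monosome_rise":
        raise ParameterError(
            f"fit_rise expects kind 'monosome_rise', got {series.kind!r}"
        )
    t, v = series.times, series.values
    if t.size < 3:
        raise FitError(f"need >= 3 time points, got {t.size}")
    if np.ptp(v) == 0:
        return DecayFit(
            k=0.0, plateau=float(v[0]), amplitude=0.0, r_squared=1.0,
            residuals=np.zeros_like(v), n_points=t.size, degenerate=True,
            kind=series.kind, label=series.label,
        )

    def resid(x):
        k, m_inf = x
        return m_inf - (m_inf - 1.0) * np.exp(-k * t) - v

    # profile M_inf (affine in the model mean) on the k grid, then polish
    ks = _k_grid()
    E = np.exp(-np.outer(ks, t))
    B = 1.0 - E
    den = (B * B).sum(axis=1)
    num = ((v[None, :] - E) * B).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.clip(np.where(den > 0, num / den, 1.0), 1.0, 1e3)
    sse = ((E + M[:, None] * B - v[None, :]) ** 2).sum(axis=1)
    i = int(np.argmin(sse))
    k0, m0 = float(ks[i]), float(M[i])
    starts = [(k0, m0), (max(k0 * 0.5, 1e-3), m0), (k0 * 2 + 1e-3, m0)]
    sol = _multistart(resid, starts, ([0.0, 1.0], [_K_MAX, 1e3]))
    k, m_inf = sol.x
    return DecayFit(
        k=float(k), plateau=float(m_inf), amplitude=float(m_inf - 1.0),
        r_squared=_r_squared(v, sol.fun), residuals=sol.fun, n_points=t.size,
        kind=series.kind, label=series.label,
    )


def build_series(
    quants: list[QuantResult],
    samples: pd.DataFrame,
    region: str = "polysome",
    label: str = "",
) -> RunoffSeries:
    """Assemble a replicate-mean fold-change series from quantified traces.

    ``samples`` maps sample_id to (treatment, runoff_time_min, replicate);
    each replicate must contain exactly one t = 0 CHX control against which
    that replicate's fold changes are computed.  The series values are the
    across-replicate means; per-replicate values are retained.
    """
    if region not in {"monosome", "polysome"}:
        raise ParameterError(f"region must be monosome or polysome, got {region!r}")
    meta = pd.DataFrame(samples).set_index("sample_id")
    by_id = {q.sample_id: q for q in quants}
    missing = set(meta.index) - set(by_id)
    if missing:
        raise DesignError(f"no quantification for sample(s): {sorted(missing)}")

    rep_series: dict[str, dict[float, float]] = {}
    for rep, grp in meta.groupby("replicate", sort=True):
        ctrl = grp[(grp["treatment"] == "CHX") & (grp["runoff_time_min"] == 0)]
        if len(ctrl) != 1:
            raise DesignError(
                f"replicate {rep!r} needs exactly one t = 0 CHX control, "
                f"found {len(ctrl)}"
            )
        q_ref = by_id[ctrl.index[0]]
        fc = {}
        for sid, row in grp.iterrows():
            fc[float(row["runoff_time_min"])] = fold_change(
                by_id[sid], q_ref, region
            )
        rep_series[str(rep)] = fc

    times = sorted(set().union(*(fc.keys() for fc in rep_series.values())))
    if len([t for t in times if t > 0]) < 2:
        raise DesignError(
            f"need >= 2 runoff time points, got {[t for t in times if t > 0]}"
        )
    mat = np.full((len(rep_series), len(times)), np.nan)
    for i, rep in enumerate(sorted(rep_series)):
        for j, t in enumerate(times):
            if t in rep_series[rep]:
                mat[i, j] = rep_series[rep][t]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.nanmean(mat, axis=0)
    kind = "polysome_decline" if region == "polysome" else "monosome_rise"
    return RunoffSeries(
        times=np.array(times), values=values, kind=kind,
        replicate_values=mat, label=label,
    )


def compare_conditions(
    fits: dict[str, DecayFit],
    pm0: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Descriptive comparison table of fitted conditions, ranked by k.

    Mirrors the standard presentation of rate constants against the
    steady-state P/M(0) per cell type; no inferential statistics.
    """
    if len(fits) < 2:
        warnings.warn(
            "compare_conditions with a single condition", RuntimeWarning,
            stacklevel=2,
        )
    rows = []
    for cond, f in fits.items():
        rows.append(
            {
                "condition": cond,
                "k_per_min": f.k,
                "plateau": f.plateau,
                "r_squared": f.r_squared,
                "pm0": pm0.get(cond, float("nan")) if pm0 else float("nan"),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        "k_per_min", ascending=False, kind="stable"
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def write_series_tsv(series: RunoffSeries, path) -> None:
    """Write a fold-change series (with replicates) as annotated TSV."""
    lines = [f"# kind: {series.kind}"]
    if series.label:
        lines.append(f"# label: {series.label}")
    header = ["time_min", "value"]
    rv = series.replicate_values
    if rv is not None:
        header += [f"rep{i + 1}" for i in range(rv.shape[0])]
    lines.append("\t".join(header))
    for j, (t, v) in enumerate(zip(series.times, series.values)):
        row = [f"{t:.17g}", f"{v:.17g}"]
        if rv is not None:
            row += [f"{rv[i, j]:.17g}" for i in range(rv.shape[0])]
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_series_tsv(path, kind: str | None = None) -> RunoffSeries:
    """Read a series TSV written by :func:`write_series_tsv` (or by hand)."""
    meta = {}
    with open(path) as fh:
        body = []
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                k, _, v = line.lstrip("#").partition(":")
                meta[k.strip()] = v.strip()
            elif line:
                body.append(line)
    df = pd.read_csv(pd.io.common.StringIO("\n".join(body)), sep="\t")
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    return RunoffSeries(
        times=df["time_min"].to_numpy(),
        values=df["value"].to_numpy(),
        kind=kind or meta.get("kind", "polysome_decline"),
        replicate_values=df[rep_cols].to_numpy().T if rep_cols else None,
        label=meta.get("label", ""),
    )
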