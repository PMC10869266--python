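"""Quantification of polysome profiles.

Baseline correction, peak detection, monosome/polysome segmentation and
area integration of A254 traces.  The central quantity is the area under
the curve (AUC) of each region: the polysome AUC approximates the number
of gradient-resolved ribosomes and the polysome-to-monosome ratio (P/M)
is the standard proxy for steady-state translational activity.

Segmentation follows the fixed-geometry rule used for fractionator traces:
the polysome region starts a constant distance (default 8.9 mm) downstream
of the 80S monosome peak centre.  That offset is configurable for other
fractionator geometries, as is the end of the usable gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import (
    DivisionError,
    IdempotenceError,
    ParameterError,
    PeakNotFoundError,
    SegmentationError,
)
from .trace_io import ProfileTrace

__all__ = [
    "Peak",
    "PeakSet",
    "RegionScheme",
    "QuantResult",
    "correct_baseline",
    "detect_peaks",
    "segment_regions",
    "integrate_regions",
    "fold_change",
    "disome_monosome_ratio",
    "rnase_units",
    "quantify_trace",
    "MONO_POLY_OFFSET_MM",
    "RNASE_UNITS_PER_UL_A260",
]

#: Constant monosome-to-polysome boundary distance in mm (downstream of the
#: 80S peak centre).
MONO_POLY_OFFSET_MM = 8.9

#: RNase1 dosing ratio in units per (microlitre of lysate x A260).
RNASE_UNITS_PER_UL_A260 = 0.19

PEAK_LABELS = ("40S", "60S", "80S", "disome", "trisome")


@dataclass(frozen=True)
class Peak:
    label: str
    center: float  # mm
    height: float  # A254 units
    window: tuple[float, float]  # mm


@dataclass
class PeakSet:
    """Detected peaks, ordered by centre, with non-overlapping windows."""

    peaks: list[Peak]

    def __post_init__(self) -> None:
        pk = sorted(self.peaks, key=lambda p: p.center)
        for p in pk:
            if p.height <= 0:
                raise ParameterError(f"peak {p.label} has non-positive height")
        for a, b in zip(pk, pk[1:]):
            if a.window[1] > b.window[0] + 1e-12:
                raise ParameterError(
                    f"peak windows overlap: {a.label} {a.window} vs "
                    f"{b.label} {b.window}"
                )
        self.peaks = pk

    def __contains__(self, label: str) -> bool:
        return any(p.label == label for p in self.peaks)

    def __getitem__(self, label: str) -> Peak:
        for p in self.peaks:
            if p.label == label:
                return p
        raise PeakNotFoundError(f"no peak labelled {label!r}")


@dataclass(frozen=True)
class RegionScheme:
    """Monosome / polysome / subunit integration windows in mm."""

    monosome_region: tuple[float, float]
    polysome_region: tuple[float, float]
    subunit_region: tuple[float, float]
    mono_poly_offset: float = MONO_POLY_OFFSET_MM

    def __post_init__(self) -> None:
        s, m, p = self.subunit_region, self.monosome_region, self.polysome_region
        for name, (lo, hi) in (("subunit", s), ("monosome", m), ("polysome", p)):
            if hi <= lo:
                raise SegmentationError(f"{name}_region {lo}..{hi} is empty")
        if not (s[1] <= m[0] + 1e-12 and m[1] <= p[0] + 1e-12):
            raise SegmentationError(
                f"regions must be ordered subunit < monosome < polysome "
                f"without overlap, got {s}, {m}, {p}"
            )


@dataclass
class QuantResult:
    """Per-sample region areas (A254*mm) and derived ratios."""

    sample_id: str
    monosome_auc: float
    polysome_auc: float
    subunit_auc: float
    pm_ratio: float
    peak_areas: dict[str, float] = field(default_factory=dict)
    gradient: str = "standard_18_50"
    total_auc: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("monosome_auc", "polysome_auc", "subunit_auc"):
            if getattr(self, name) < 0:
                raise SegmentationError(f"{name} is negative")


def _edge_line(pos: np.ndarray, a: np.ndarray, frac: float = 0.02) -> np.ndarray:
    """Line through the mean of the first and last ``frac`` of points."""
    n_edge = max(2, int(round(frac * pos.size)))
    x0, y0 = pos[:n_edge].mean(), a[:n_edge].mean()
    x1, y1 = pos[-n_edge:].mean(), a[-n_edge:].mean()
    slope = (y1 - y0) / (x1 - x0)
    return y0 + slope * (pos - x0)


def _rolling_min_baseline(pos: np.ndarray, a: np.ndarray, window: float) -> np.ndarray:
    step = float(np.median(np.diff(pos)))
    half = max(1, int(round(window / step / 2)))
    n = a.size
    base = np.empty(n)
    for i in range(n):
        base[i] = a[max(0, i - half): i + half + 1].min()
    # smooth the staircase with a same-width moving average
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    return np.convolve(np.pad(base, half, mode="edge"), kernel, mode="valid")


def correct_baseline(
    trace: ProfileTrace,
    method: str = "linear_endpoints",
    window: float = 5.0,
) -> ProfileTrace:
    """Subtract the optical baseline from a raw trace.

    ``linear_endpoints`` (default) draws a line through the first and last
    2 % of points — the simplest defensible model for a UV trace whose ends
    are signal-free.  ``rolling_minimum`` tracks a drifting baseline with a
    rolling minimum of the given ``window`` (mm).  The corrected trace is
    clipped at zero and flagged ``baseline_corrected``.
    """
    if trace.baseline_corrected:
        raise IdempotenceError(
            f"trace {trace.sample_id!r} is already baseline-corrected"
        )
    if window <= 0:
        raise ParameterError(f"window must be > 0 mm, got {window}")
    pos, a = trace.positions, trace.absorbance
    if method == "linear_endpoints":
        base = _edge_line(pos, a)
    elif method == "rolling_minimum":
        base = _rolling_min_baseline(pos, a, window)
    else:
        raise ParameterError(f"unknown baseline method {method!r}")
    corrected = np.maximum(a - base, 0.0)
    return trace.with_absorbance(corrected, baseline_corrected=True)


def _parabolic_refine(pos: np.ndarray, a: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through points i-1, i, i+1 (centre, height)."""
    if i == 0 or i == pos.size - 1:
        return float(pos[i]), float(a[i])
    coeff = np.polyfit(pos[i - 1: i + 2], a[i - 1: i + 2], 2)
    if coeff[0] >= 0:  # degenerate (not concave) — keep the grid point
        return float(pos[i]), float(a[i])
    xv = -coeff[1] / (2 * coeff[0])
    if not (pos[i - 1] <= xv <= pos[i + 1]):
        return float(pos[i]), float(a[i])
    yv = np.polyval(coeff, xv)
    return float(xv), float(yv)


def detect_peaks(
    trace: ProfileTrace,
    search_windows: dict[str, tuple[float, float]],
    min_prominence: float = 0.0,
    required: set[str] | None = None,
) -> PeakSet:
    """Find the most prominent local maximum inside each labelled window.

    Peak centres are refined by a 3-point parabolic fit.  A window in
    ``required`` (default: all windows) without a qualifying maximum raises
    :class:`PeakNotFoundError` naming the label.
    """
    if not trace.baseline_corrected:
        raise ParameterError("detect_peaks requires a baseline-corrected trace")
    pos, a = trace.positions, trace.absorbance
    if required is None:
        required = set(search_windows)
    idx, props = signal.find_peaks(a, prominence=max(min_prominence, 1e-300))
    peaks: list[Peak] = []
    for label, (lo, hi) in search_windows.items():
        in_win = idx[(pos[idx] >= lo) & (pos[idx] <= hi)]
        if in_win.size == 0:
            if label in required:
                raise PeakNotFoundError(
                    f"no peak with prominence >= {min_prominence} in window "
                    f"[{lo}, {hi}] mm for label {label!r}"
                )
            continue
        prom = props["prominences"][np.isin(idx, in_win)]
        best = int(in_win[np.argmax(prom)])
        center, height = _parabolic_refine(pos, a, best)
        if height <= 0:
            if label in required:
                raise PeakNotFoundError(f"peak {label!r} has zero height")
            continue
        peaks.append(Peak(label, center, height, (lo, hi)))
    return PeakSet(peaks)


def segment_regions(
    peaks: PeakSet,
    mono_poly_offset: float = MONO_POLY_OFFSET_MM,
    gradient_end: float = 60.0,
    gradient_start: float = 0.0,
) -> RegionScheme:
    """Derive integration regions from the 80S peak position.

    The monosome region spans from the start of the 80S search window to
    the 80S centre plus ``mono_poly_offset``; everything from there to
    ``gradient_end`` is polysomes; everything left of the monosome region
    is ribosomal subunits.  Material beyond ``gradient_end`` (pellet) is
    excluded.
    """
    if mono_poly_offset < 0:
        raise ParameterError("mono_poly_offset must be >= 0 mm")
    if "80S" not in peaks:
        raise PeakNotFoundError("segmentation requires an 80S peak")
    p80 = peaks["80S"]
    boundary = p80.center + mono_poly_offset
    if boundary >= gradient_end:
        raise SegmentationError(
            f"80S centre {p80.center:.2f} + offset {mono_poly_offset} mm "
            f"reaches past gradient end {gradient_end} mm"
        )
    mono_start = p80.window[0]
    if mono_start <= gradient_start:
        raise SegmentationError(
            "80S window start must lie inside the gradient to leave a "
            "subunit region"
        )
    return RegionScheme(
        monosome_region=(mono_start, boundary),
        polysome_region=(boundary, gradient_end),
        subunit_region=(gradient_start, mono_start),
        mono_poly_offset=mono_poly_offset,
    )


def _auc(pos: np.ndarray, a: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal area over [lo, hi], interpolating at the boundaries.

    Exact for the piecewise-linear interpolant of the sampled trace, so
    region areas are additive to machine precision.
    """
    if lo < pos[0] - 1e-9 or hi > pos[-1] + 1e-9:
        raise SegmentationError(
            f"region [{lo}, {hi}] outside trace span [{pos[0]}, {pos[-1]}]"
        )
    lo, hi = max(lo, pos[0]), min(hi, pos[-1])
    inner = (pos > lo) & (pos < hi)
    xs = np.concatenate(([lo], pos[inner], [hi]))
    ys = np.interp(xs, pos, a)
    return float(np.trapezoid(ys, xs))


def integrate_regions(
    trace: ProfileTrace,
    regions: RegionScheme,
    peaks: PeakSet | None = None,
) -> QuantResult:
    """Integrate region areas (trapezoid on the raw grid, no smoothing).

    ``pm_ratio`` is polysome/monosome AUC; a zero monosome AUC yields NaN
    with a warning rather than an exception so batch runs survive
    degenerate inputs.  If ``peaks`` is given, each peak window is also
    integrated into ``peak_areas``.
    """
    if not trace.baseline_corrected:
        raise ParameterError("integrate_regions requires a baseline-corrected trace")
    pos, a = trace.positions, trace.absorbance
    mono = _auc(pos, a, *regions.monosome_region)
    poly = _auc(pos, a, *regions.polysome_region)
    sub = _auc(pos, a, *regions.subunit_region)
    if mono > 0:
        pm = poly / mono
    else:
        warnings.warn(
            f"sample {trace.sample_id!r}: monosome AUC is zero, P/M is NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        pm = float("nan")
    peak_areas = {}
    if peaks is not None:
        for p in peaks.peaks:
            peak_areas[p.label] = _auc(pos, a, *p.window)
    return QuantResult(
        sample_id=trace.sample_id,
        monosome_auc=mono,
        polysome_auc=poly,
        subunit_auc=sub,
        pm_ratio=pm,
        peak_areas=peak_areas,
        gradient=trace.gradient,
        total_auc=float(np.trapezoid(a, pos)),
    )


def fold_change(quant_t: QuantResult, quant_ref: QuantResult, region: str) -> float:
    """Region AUC at time t relative to the t = 0 CHX reference."""
    if region not in {"monosome", "polysome"}:
        raise ParameterError(f"region must be monosome or polysome, got {region!r}")
    if quant_t.gradient != quant_ref.gradient:
        raise ParameterError(
            f"fold change across gradient types "
            f"({quant_t.gradient} vs {quant_ref.gradient})"
        )
    attr = f"{region}_auc"
    ref = getattr(quant_ref, attr)
    if ref == 0:
        raise DivisionError(f"reference {attr} is zero")
    return getattr(quant_t, attr) / ref


def disome_monosome_ratio(quant: QuantResult) -> float:
    """Disome-to-80S area ratio from a high-resolution gradient."""
    if quant.gradient != "highres_5_25":
        raise ParameterError(
            "disome/80S quantification requires a highres_5_25 gradient"
        )
    for label in ("80S", "disome"):
        if label not in quant.peak_areas:
            raise PeakNotFoundError(f"peak_areas lacks {label!r}")
    a80 = quant.peak_areas["80S"]
    if a80 == 0:
        raise DivisionError("80S peak area is zero")
    return quant.peak_areas["disome"] / a80


def rnase_units(a260: float, lysate_volume: float) -> float:
    """RNase1 units for a lysate, at 0.19 U per microlitre and A260 unit."""
    if a260 <= 0 or lysate_volume <= 0:
        raise ParameterError("a260 and lysate_volume must be positive")
    return RNASE_UNITS_PER_UL_A260 * a260 * lysate_volume


def quantify_trace(
    trace: ProfileTrace,
    search_windows: dict[str, tuple[float, float]],
    mono_poly_offset: float = MONO_POLY_OFFSET_MM,
    gradient_end: float = 60.0,
    baseline_method: str = "linear_endpoints",
    min_prominence: float = 0.0,
    required_peaks: set[str] | None = None,
) -> QuantResult:
    """Baseline-correct, detect peaks, segment and integrate in one call."""
    corrected = (
        trace
        if trace.baseline_corrected
        else correct_baseline(trace, method=baseline_method)
    )
    if required_peaks is None:
        required_peaks = {"80S"} & set(search_windows)
    peaks = detect_peaks(
        corrected, search_windows, min_prominence, required=required_peaks
    )
    regions = segment_regions(
        peaks, mono_poly_offset=mono_poly_offset, gradient_end=gradient_end
    )
    return integrate_regions(corrected, regions, peaks=peaks)
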