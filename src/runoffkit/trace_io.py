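"""Reading and writing polysome-profile absorbance traces.

A trace is the A254 read-out of a fractionated sucrose gradient, sampled
against the distance from the gradient top in millimetres.  Files are plain
TSV/CSV with two numeric columns (``position_mm``, ``a254``) and optional
``# key: value`` metadata header lines, so they stay usable by generic
plotting tools.  Positions are always millimetres from the top; traces
recorded in fraction numbers must be converted upstream.

No smoothing or resampling happens at I/O time — raw data stay pristine and
all processing lives in :mod:`runoffkit.profile_quant`.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError, GeometryError

__all__ = [
    "ProfileTrace",
    "SampleSheet",
    "read_trace",
    "write_trace",
    "read_sample_sheet",
    "TREATMENTS",
    "GRADIENTS",
    "MIN_POINTS",
]

#: Recognized pharmacological / enzymatic treatments.
TREATMENTS = frozenset(
    {"CHX", "HRN", "HRN+EDTA", "HRN+PMY", "RNase1", "NMDA", "control"}
)

#: Gradient geometries: the standard 18–50 % (w/v) sucrose gradient and the
#: high-resolution 5–25 % gradient that resolves 80S and disome peaks.
GRADIENTS = frozenset({"standard_18_50", "highres_5_25"})

#: Minimum number of sampled points for a usable trace.
MIN_POINTS = 32

# Treatments that by definition involve no harringtonine runoff; their
# runoff time must be 0.  RNase1 and NMDA traces may carry either a zero
# (steady state) or nonzero (post-runoff lysate) time.
_NO_RUNOFF = frozenset({"CHX", "control"})
_RUNOFF_ONLY = frozenset({"HRN", "HRN+EDTA", "HRN+PMY"})

_BASELINE_TOL = 1e-9


@dataclass(frozen=True)
class ProfileTrace:
    """One A254 absorbance trace with its sample metadata.

    Parameters
    ----------
    positions
        Millimetres from the gradient top, strictly increasing, >= 32 points.
    absorbance
        A254 in arbitrary units, same length as ``positions``, finite.
    treatment
        One of :data:`TREATMENTS`.
    runoff_time
        Harringtonine incubation time in minutes (0 for no-runoff controls).
    gradient
        One of :data:`GRADIENTS`.
    baseline_corrected
        Set by :func:`runoffkit.profile_quant.correct_baseline`; corrected
        traces must be non-negative to within 1e-9.
    """

    positions: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""
    treatment: str = "CHX"
    runoff_time: float = 0.0
    gradient: str = "standard_18_50"
    baseline_corrected: bool = False
    cell_type: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "absorbance", a)
        if pos.ndim != 1 or a.ndim != 1 or pos.shape != a.shape:
            raise FormatError(
                f"positions and absorbance must be equal-length 1-D arrays, "
                f"got {pos.shape} and {a.shape}"
            )
        if pos.size < MIN_POINTS:
            raise FormatError(
                f"trace has {pos.size} points, need at least {MIN_POINTS}"
            )
        if not np.all(np.isfinite(pos)):
            raise GeometryError("non-finite positions in trace")
        if np.any(np.diff(pos) <= 0):
            i = int(np.argmax(np.diff(pos) <= 0))
            raise GeometryError(
                f"positions must be strictly increasing (violation after "
                f"index {i}: {pos[i]} -> {pos[i + 1]})"
            )
        if not np.all(np.isfinite(a)):
            raise FormatError("non-finite absorbance values in trace")
        if self.baseline_corrected and a.min() < -_BASELINE_TOL:
            raise FormatError(
                f"baseline-corrected trace has min absorbance {a.min():g} "
                f"< -{_BASELINE_TOL:g}"
            )
        if self.treatment not in TREATMENTS:
            raise FormatError(
                f"unknown treatment {self.treatment!r}; expected one of "
                f"{sorted(TREATMENTS)}"
            )
        if self.gradient not in GRADIENTS:
            raise FormatError(f"unknown gradient {self.gradient!r}")
        if self.runoff_time < 0:
            raise FormatError("runoff_time must be >= 0 minutes")
        if self.treatment in _NO_RUNOFF and self.runoff_time != 0:
            raise FormatError(
                f"{self.treatment} is a no-runoff control but "
                f"runoff_time = {self.runoff_time} min"
            )
        if self.treatment in _RUNOFF_ONLY and self.runoff_time == 0:
            raise FormatError(
                f"{self.treatment} requires a positive runoff_time"
            )

    @property
    def span(self) -> tuple[float, float]:
        """(first, last) position in mm."""
        return float(self.positions[0]), float(self.positions[-1])

    def with_absorbance(self, absorbance: np.ndarray, **changes) -> "ProfileTrace":
        """Copy of this trace with new absorbance values (and field changes)."""
        return replace(self, absorbance=np.asarray(absorbance, float), **changes)


# Metadata header keys <-> ProfileTrace fields.
_HEADER_FIELDS = {
    "sample_id": str,
    "treatment": str,
    "runoff_time_min": float,
    "gradient": str,
    "baseline_corrected": lambda s: s.strip().lower() in {"true", "1", "yes"},
    "cell_type": str,
    "replicate": str,
}
_FIELD_TO_HEADER = {
    "sample_id": "sample_id",
    "treatment": "treatment",
    "runoff_time": "runoff_time_min",
    "gradient": "gradient",
    "baseline_corrected": "baseline_corrected",
    "cell_type": "cell_type",
    "replicate": "replicate",
}


def _sniff_delimiter(sample_line: str) -> str:
    return "\t" if sample_line.count("\t") >= sample_line.count(",") else ","


def read_trace(path, dialect: str = "autodetect", **defaults) -> ProfileTrace:
    """Read a trace file into a validated :class:`ProfileTrace`.

    ``# key: value`` header lines populate the metadata fields and override
    any ``defaults`` passed by the caller (e.g. from a sample sheet).
    Non-monotone positions raise :class:`GeometryError` — they are an
    acquisition fault, never silently re-sorted.
    """
    if dialect not in {"csv", "tsv", "autodetect"}:
        raise FormatError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict[str, object] = {}
    data_lines: list[tuple[int, str]] = []
    with open(path, "r", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    key = key.strip()
                    if key in _HEADER_FIELDS:
                        conv = _HEADER_FIELDS[key]
                        field_name = (
                            "runoff_time" if key == "runoff_time_min" else key
                        )
                        try:
                            meta[field_name] = conv(val.strip())
                        except ValueError as exc:
                            raise FormatError(
                                f"{path}:{lineno}: bad header value for "
                                f"{key!r}: {val.strip()!r}"
                            ) from exc
                continue
            data_lines.append((lineno, line))
    if not data_lines:
        raise FormatError(f"{path}: no data rows")
    delim = "\t" if dialect == "tsv" else "," if dialect == "csv" else (
        _sniff_delimiter(data_lines[0][1])
    )
    reader = csv.reader(io.StringIO("\n".join(l for _, l in data_lines)),
                        delimiter=delim)
    positions, absorbance = [], []
    for (lineno, _), row in zip(data_lines, reader):
        row = [c for c in row if c.strip() != ""]
        if len(row) < 2:
            # A single header row naming the columns is tolerated.
            if not positions and any(not _is_number(c) for c in row):
                continue
            raise FormatError(f"{path}:{lineno}: expected two numeric columns")
        if not positions and not (_is_number(row[0]) and _is_number(row[1])):
            continue  # column-name header row
        try:
            positions.append(float(row[0]))
            absorbance.append(float(row[1]))
        except ValueError as exc:
            raise FormatError(
                f"{path}:{lineno}: non-numeric cell in row {row!r}"
            ) from exc
    if len(positions) < MIN_POINTS:
        raise FormatError(
            f"{path}: {len(positions)} data rows, need at least {MIN_POINTS}"
        )
    fields = dict(defaults)
    fields.update(meta)  # header wins over sample-sheet defaults
    return ProfileTrace(np.array(positions), np.array(absorbance), **fields)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_trace(trace: ProfileTrace, path) -> None:
    """Write a trace as TSV with a ``#`` metadata header.

    Values are written with 17 significant digits so a write/read round
    trip reproduces the trace to better than 1e-12.  Empty string fields
    are omitted from the header and fall back to defaults on re-read.
    """
    path = Path(path)
    lines = []
    for field_name, header_key in _FIELD_TO_HEADER.items():
        val = getattr(trace, field_name)
        if val == "" or val is None:
            continue
        lines.append(f"# {header_key}: {val}")
    lines.append("position_mm\ta254")
    for x, y in zip(trace.positions, trace.absorbance):
        lines.append(f"{x:.17g}\t{y:.17g}")
    path.write_text("\n".join(lines) + "\n")


@dataclass
class SampleSheet:
    """Metadata table linking trace files to their experimental conditions.

    Columns: ``path, sample_id, treatment, runoff_time_min, gradient,
    cell_type, replicate``.  Sample ids must be unique.
    """

    records: pd.DataFrame = field(repr=False)

    REQUIRED = ("path", "sample_id", "treatment", "runoff_time_min",
                "gradient", "cell_type", "replicate")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise DesignError(f"duplicate sample_id(s): {dups}")
        df = df.copy()
        df["runoff_time_min"] = df["runoff_time_min"].astype(float)
        self.records = df

    def load_traces(self, root=None) -> dict[str, ProfileTrace]:
        """Read every referenced trace, applying sheet metadata as defaults."""
        out = {}
        for _, row in self.records.iterrows():
            p = Path(row["path"])
            if root is not None and not p.is_absolute():
                p = Path(root) / p
            out[row["sample_id"]] = read_trace(
                p,
                sample_id=row["sample_id"],
                treatment=row["treatment"],
                runoff_time=float(row["runoff_time_min"]),
                gradient=row["gradient"],
                cell_type=str(row["cell_type"]),
                replicate=str(row["replicate"]),
            )
        return out


def read_sample_sheet(path) -> SampleSheet:
    """Read a sample sheet CSV."""
    try:
        df = pd.read_csv(path, comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse sample sheet {path}: {exc}") from exc
    return SampleSheet(df)
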