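"""Reading, baseline-correcting and transforming optical melting curves.

A melting curve is absorbance vs temperature plus a total strand
concentration.  Linear upper/lower baselines are fit to the first/last
fraction of points; the fraction of maximal base pairs is

    X(T) = (upper(T) - A(T)) / (upper(T) - lower(T))

(unclamped: the fitting objective must see real noise excursions), and the
experimental melting temperature is found by linear interpolation of the
first 0.5 crossing.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    DegenerateBaselineError,
    NoTransitionError,
    ParseError,
    ValidationError,
)


@dataclass
class MeltingCurve:
    """Absorbance vs temperature at one strand concentration.

    Temperatures in deg C (strictly increasing), absorbances in AU,
    strand_concentration C_T in mol/L (total strands).
    """

    curve_id: str
    duplex_id: str
    temperatures: np.ndarray
    absorbances: np.ndarray
    strand_concentration: float

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.temperatures.shape != self.absorbances.shape or self.temperatures.ndim != 1:
            raise ValidationError(
                f"curve {self.curve_id!r}: temperature/absorbance arrays must be "
                "1-D and the same length"
            )
        if self.temperatures.size < 2:
            raise ValidationError(f"curve {self.curve_id!r}: need at least 2 points")
        if not np.all(np.isfinite(self.temperatures)) or not np.all(
            np.isfinite(self.absorbances)
        ):
            raise ValidationError(f"curve {self.curve_id!r}: non-finite values")
        if np.any(np.diff(self.temperatures) <= 0):
            dup = np.nonzero(np.diff(self.temperatures) == 0)[0]
            if dup.size:
                raise ValidationError(
                    f"curve {self.curve_id!r}: duplicated temperatures at sorted "
                    f"rows {(dup + 1).tolist()}"
                )
            raise ValidationError(f"curve {self.curve_id!r}: temperatures not increasing")
        if self.strand_concentration <= 0:
            raise ValidationError(f"curve {self.curve_id!r}: C_T must be positive")

    @property
    def n_points(self) -> int:
        return int(self.temperatures.size)


@dataclass
class BaselineFit:
    """Linear upper/lower baselines: A = m*T + b, slopes in AU/degC."""

    lower_slope: float
    lower_intercept: float
    upper_slope: float
    upper_intercept: float
    n_lower: int
    n_upper: int
    degenerate: bool = False

    def lower(self, T) -> np.ndarray:
        return self.lower_slope * np.asarray(T, float) + self.lower_intercept

    def upper(self, T) -> np.ndarray:
        return self.upper_slope * np.asarray(T, float) + self.upper_intercept


@dataclass
class FractionCurve:
    """Fraction of maximal base pairs vs temperature (deg C), unclamped."""

    curve_id: str
    duplex_id: str
    temperatures: np.ndarray
    fractions: np.ndarray
    strand_concentration: float

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if not np.all(np.isfinite(self.fractions)):
            raise ValidationError(f"curve {self.curve_id!r}: non-finite fractions")


def read_melt_curve(
    path: str | Path,
    curve_id: str = "",
    duplex_id: str = "",
    strand_concentration: float = 1.0,
) -> MeltingCurve:
    """Parse a two-column (T deg C, A in AU) CSV melting curve.

    '#' starts a comment; a single non-numeric first row is treated as a
    header.  Points are returned sorted by temperature.  Non-numeric data
    rows and duplicated temperatures raise errors naming the offending line.
    """
    path = Path(path)
    temps: List[float] = []
    absorb: List[float] = []
    lines: List[Tuple[int, float]] = []  # (lineno, T) for duplicate reporting
    header_seen = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: expected two comma-separated columns")
            try:
                t, a = float(parts[0]), float(parts[1])
            except ValueError:
                if not header_seen and not temps:
                    header_seen = True
                    continue
                raise ParseError(f"{path}: line {lineno}: non-numeric row {line!r}") from None
            if not (np.isfinite(t) and np.isfinite(a)):
                raise ParseError(f"{path}: line {lineno}: non-finite value in {line!r}")
            temps.append(t)
            absorb.append(a)
            lines.append((lineno, t))
    if len(temps) < 2:
        raise ParseError(f"{path}: fewer than 2 data points")
    order = np.argsort(temps, kind="stable")
    t_sorted = np.asarray(temps)[order]
    dup = np.nonzero(np.diff(t_sorted) == 0)[0]
    if dup.size:
        i = int(order[dup[0]])
        j = int(order[dup[0] + 1])
        raise ValidationError(
            f"{path}: duplicated temperature {t_sorted[dup[0]]:g} on lines "
            f"{lines[i][0]} and {lines[j][0]}"
        )
    return MeltingCurve(
        curve_id=curve_id or path.stem,
        duplex_id=duplex_id,
        temperatures=t_sorted,
        absorbances=np.asarray(absorb)[order],
        strand_concentration=strand_concentration,
    )


def write_melt_curve(curve: MeltingCurve, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("temperature_C,absorbance_AU\n")
        for t, a in zip(curve.temperatures, curve.absorbances):
            fh.write(f"{t:.6g},{a:.8g}\n")


def write_fraction_curve(curve: FractionCurve, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("temperature_C,fraction_paired\n")
        for t, x in zip(curve.temperatures, curve.fractions):
            fh.write(f"{t:.6g},{x:.8g}\n")


def _fit_line(T: np.ndarray, A: np.ndarray, which: str, curve_id: str) -> Tuple[float, float]:
    if T.size < 2:
        raise ValidationError(
            f"curve {curve_id!r}: {which} baseline window has {T.size} point(s); need >= 2"
        )
    if np.ptp(T) == 0:
        raise ValidationError(
            f"curve {curve_id!r}: {which} baseline window has zero temperature spread"
        )
    slope, intercept = np.polyfit(T, A, 1)
    return float(slope), float(intercept)


def fit_baselines(
    curve: MeltingCurve, lower_frac: float = 0.10, upper_frac: float = 0.10
) -> BaselineFit:
    """Least-squares lines through the first ``lower_frac`` (low-temperature,
    double-helix) and last ``upper_frac`` (high-temperature, random-coil)
    fractions of points.

    Window sizes are fractions of the point count, overridable per curve to
    mirror manual baseline adjustment; there is no automatic window search.
    Sets ``degenerate`` when the upper baseline fails to lie above the lower
    one over the curve's temperature span.
    """
    if not (0 < lower_frac < 1 and 0 < upper_frac < 1):
        raise ValidationError("baseline fractions must lie in (0, 1)")
    n = curve.n_points
    n_lo = int(round(lower_frac * n))
    n_up = int(round(upper_frac * n))
    T, A = curve.temperatures, curve.absorbances
    m_l, b_l = _fit_line(T[:n_lo], A[:n_lo], "lower", curve.curve_id)
    m_u, b_u = _fit_line(T[n - n_up :], A[n - n_up :], "upper", curve.curve_id)
    span = np.array([T[0], T[-1]])
    degenerate = bool(np.any(m_u * span + b_u <= m_l * span + b_l))
    return BaselineFit(m_l, b_l, m_u, b_u, n_lo, n_up, degenerate)


def to_fraction_paired(curve: MeltingCurve, baselines: BaselineFit) -> FractionCurve:
    """Transform absorbance to fraction of maximal pairs, unclamped."""
    T = curve.temperatures
    denom = baselines.upper(T) - baselines.lower(T)
    if np.any(denom <= 0):
        bad = T[np.nonzero(denom <= 0)[0][0]]
        raise DegenerateBaselineError(
            f"curve {curve.curve_id!r}: upper baseline does not exceed lower "
            f"baseline at T={bad:g} deg C"
        )
    X = (baselines.upper(T) - curve.absorbances) / denom
    return FractionCurve(
        curve.curve_id, curve.duplex_id, T.copy(), X, curve.strand_concentration
    )


def interpolate_tm(curve: FractionCurve) -> float:
    """Experimental Tm (deg C): linear interpolation of the first X=0.5 crossing.

    Exact grid hits return that temperature.  Multiple crossings (noise) use
    the first by increasing temperature and emit a warning.
    """
    T, X = curve.temperatures, curve.fractions
    f = X - 0.5
    events: List[float] = []
    for i in range(T.size - 1):
        if f[i] == 0.0:
            events.append(float(T[i]))
        elif f[i] * f[i + 1] < 0.0:
            events.append(float(T[i] + (T[i + 1] - T[i]) * (0.5 - X[i]) / (X[i + 1] - X[i])))
    if f[-1] == 0.0:
        events.append(float(T[-1]))
    if not events:
        raise NoTransitionError(f"curve {curve.curve_id!r} never crosses X = 0.5")
    if len(events) > 1:
        warnings.warn(
            f"curve {curve.curve_id!r}: {len(events)} crossings of X=0.5; using the "
            "first by increasing temperature",
            stacklevel=2,
        )
    return events[0]


# ---------------------------------------------------------------------------
# Manifest handling
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("curve_id", "duplex_id", "top_strand", "path", "c_t")


@dataclass
class ManifestRow:
    curve_id: str
    duplex_id: str
    top_strand: str
    path: Path
    c_t: float
    lower_frac: Optional[float] = None
    upper_frac: Optional[float] = None


def read_manifest(path: str | Path) -> List[ManifestRow]:
    """Read a dataset manifest CSV.

    Required columns: curve_id, duplex_id, top_strand, path, c_t.  Optional:
    lower_frac, upper_frac (per-curve baseline-window overrides).  Relative
    melt-file paths are resolved against the manifest's directory.
    """
    path = Path(path)
    rows: List[ManifestRow] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValidationError(f"{path}: manifest missing columns {sorted(missing)}")
        for lineno, rec in enumerate(reader, start=2):
            try:
                c_t = float(rec["c_t"])
            except (TypeError, ValueError):
                raise ParseError(f"{path}: line {lineno}: non-numeric c_t") from None
            melt_path = Path(rec["path"])
            if not melt_path.is_absolute():
                melt_path = path.parent / melt_path
            rows.append(
                ManifestRow(
                    curve_id=rec["curve_id"],
                    duplex_id=rec["duplex_id"],
                    top_strand=rec["top_strand"].strip().upper(),
                    path=melt_path,
                    c_t=c_t,
                    lower_frac=float(rec["lower_frac"]) if rec.get("lower_frac") else None,
                    upper_frac=float(rec["upper_frac"]) if rec.get("upper_frac") else None,
                )
            )
    if not rows:
        raise ValidationError(f"{path}: manifest has no rows")
    return rows


def write_manifest(rows: Sequence[ManifestRow], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS + ("lower_frac", "upper_frac"))
        for r in rows:
            rel = r.path
            try:
                rel = r.path.relative_to(path.parent)
            except ValueError:
                pass
            writer.writerow(
                [
                    r.curve_id,
                    r.duplex_id,
                    r.top_strand,
                    str(rel),
                    f"{r.c_t:.8g}",
                    "" if r.lower_frac is None else f"{r.lower_frac:g}",
                    "" if r.upper_frac is None else f"{r.upper_frac:g}",
                ]
            )


def load_melt_curves(
    manifest_path: str | Path,
) -> List[Tuple[ManifestRow, MeltingCurve]]:
    """Read every melt file referenced by a manifest."""
    out = []
    for row in read_manifest(manifest_path):
        if not row.path.exists():
            raise ValidationError(
                f"manifest row {row.curve_id!r}: melt file not found: {row.path}"
            )
        curve = read_melt_curve(row.path, row.curve_id, row.duplex_id, row.c_t)
        out.append((row, curve))
    return out
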