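"""Reading, writing, unit conversion and smoothing of CD/UV spectra.

A :class:`Spectrum` is a strictly ascending wavelength grid (nm) with one
signal channel and a unit tag.  Circular-dichroism channels come in three
interconvertible units — instrument ellipticity (millidegrees), differential
absorbance ΔA = A_L − A_R, and differential molar absorption Δε = ΔA/(c·l) —
while plain absorption channels come as absorbance A or molar absorption
ε = A/(c·l).  Conversions between the CD family and the absorption family are
not defined and raise.

Files are UTF-8 text: '#'-prefixed ``key: value`` header lines followed by
two-column wavelength,signal rows (comma- or tab-separated).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MDEG_PER_DELTA_A",
    "Unit",
    "Spectrum",
    "SolutionSpec",
    "TitrationSeries",
    "PeakLocation",
    "read_spectrum",
    "write_spectrum",
    "read_manifest",
    "write_manifest",
    "convert_units",
    "subtract_blank",
    "fft_lowpass",
    "find_lambda_max",
]

#: Millidegrees of ellipticity per unit of differential absorbance.
#: θ[deg] = 32.982 · ΔA, the standard CD spectropolarimeter convention
#: (θ = 180·ln(10)/(4π) · ΔA degrees).
MDEG_PER_DELTA_A = 32982.0

#: Default low-pass cutoff as a fraction of the Nyquist frequency.
DEFAULT_CUTOFF_FRACTION = 0.15


class Unit(str, Enum):
    """Signal units a :class:`Spectrum` may carry."""

    ELLIPTICITY_MDEG = "ellipticity_mdeg"
    DELTA_ABSORBANCE = "delta_absorbance"
    DELTA_EPSILON = "delta_epsilon"          # M^-1 cm^-1
    ABSORBANCE = "absorbance"
    MOLAR_ABSORPTION = "molar_absorption"    # M^-1 cm^-1

    @property
    def is_cd(self) -> bool:
        return self in (
            Unit.ELLIPTICITY_MDEG,
            Unit.DELTA_ABSORBANCE,
            Unit.DELTA_EPSILON,
        )

    @property
    def is_molar(self) -> bool:
        return self in (Unit.DELTA_EPSILON, Unit.MOLAR_ABSORPTION)


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed."""


@dataclass(frozen=True)
class Spectrum:
    """One spectral channel on a strictly ascending wavelength grid.

    Parameters
    ----------
    wavelengths : array of float
        Wavelength grid in nm, strictly increasing and finite.
    values : array of float
        Signal per grid point, same length as ``wavelengths``.
    unit : Unit
        Signal unit tag.
    pathlength_cm : float, optional
        Cell pathlength in cm; required for concentration-normalised
        conversions when no :class:`SolutionSpec` is supplied.
    meta : dict
        Free-form provenance (instrument settings, concentrations, ...).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    unit: Unit = Unit.ELLIPTICITY_MDEG
    pathlength_cm: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D")
        if wl.size != vals.size:
            raise ValueError(
                f"length mismatch: {wl.size} wavelengths, {vals.size} values"
            )
        if wl.size == 0:
            raise ValueError("empty spectrum")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(vals)):
            raise ValueError("non-finite wavelength or signal value")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "unit", Unit(self.unit))

    def __len__(self) -> int:
        return self.wavelengths.size

    def with_values(self, values: np.ndarray, unit: Unit | None = None) -> "Spectrum":
        """Copy of this spectrum with new values (and optionally a new unit)."""
        return Spectrum(
            self.wavelengths.copy(),
            np.asarray(values, dtype=float),
            unit if unit is not None else self.unit,
            self.pathlength_cm,
            dict(self.meta),
        )

    def value_at(self, wavelength: float) -> float:
        """Signal linearly interpolated at ``wavelength`` (nm)."""
        wl = self.wavelengths
        if not (wl[0] <= wavelength <= wl[-1]):
            raise ValueError(
                f"wavelength {wavelength} nm outside grid [{wl[0]}, {wl[-1]}]"
            )
        return float(np.interp(wavelength, wl, self.values))

    def is_uniform(self, rtol: float = 1e-8) -> bool:
        """True if the wavelength grid has a constant step."""
        if len(self) < 3:
            return True
        steps = np.diff(self.wavelengths)
        return bool(np.all(np.abs(steps - steps[0]) <= rtol * abs(steps[0])))


@dataclass(frozen=True)
class SolutionSpec:
    """Total concentrations and pathlength of one measured solution.

    guest_total and host_total are molar; pathlength_cm in cm.
    """

    guest_total: float
    host_total: float
    pathlength_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.guest_total < 0 or self.host_total < 0:
            raise ValueError("concentrations must be non-negative")
        if self.pathlength_cm <= 0:
            raise ValueError("pathlength must be positive")


class TitrationSeries:
    """An ordered host titration at fixed guest concentration.

    Points are canonically sorted by total host concentration.  The guest
    concentration must be identical across points (the titration design:
    vary the cyclodextrin while keeping the guest constant).
    """

    def __init__(self, points: Iterable[tuple[SolutionSpec, Spectrum]]):
        pts = sorted(points, key=lambda p: p[0].host_total)
        if not pts:
            raise ValueError("empty titration series")
        g0 = pts[0][0].guest_total
        if g0 <= 0:
            raise ValueError("guest_total must be positive for a titration")
        for sol, _ in pts:
            if not math.isclose(sol.guest_total, g0, rel_tol=1e-9):
                raise ValueError(
                    "guest_total must be constant across a titration series"
                )
        self.points: list[tuple[SolutionSpec, Spectrum]] = pts

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    @property
    def guest_total(self) -> float:
        return self.points[0][0].guest_total

    @property
    def host_totals(self) -> np.ndarray:
        return np.array([sol.host_total for sol, _ in self.points])

    @property
    def pathlengths(self) -> np.ndarray:
        return np.array([sol.pathlength_cm for sol, _ in self.points])

    @property
    def has_common_grid(self) -> bool:
        wl0 = self.points[0][1].wavelengths
        return all(
            len(s) == len(wl0) and np.array_equal(s.wavelengths, wl0)
            for _, s in self.points
        )

    @property
    def wavelengths(self) -> np.ndarray:
        if not self.has_common_grid:
            raise ValueError("titration points are not on a common grid")
        return self.points[0][1].wavelengths

    def signal_matrix(self) -> np.ndarray:
        """(n_points, n_wavelengths) matrix of signals on the common grid."""
        if not self.has_common_grid:
            raise ValueError("titration points are not on a common grid")
        return np.vstack([s.values for _, s in self.points])

    def signal_at(self, wavelength: float) -> np.ndarray:
        """Per-point signal interpolated at one wavelength."""
        return np.array([s.value_at(wavelength) for _, s in self.points])


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = {"unit", "pathlength_cm", "guest_M", "host_M"}


def read_spectrum(path: str | Path, dialect: str = "csv") -> Spectrum:
    """Read a two-column spectrum file.

    Both dialects share the layout '#'-header plus two numeric columns;
    ``jasco_text`` differs only in its default unit (ellipticity in
    millidegrees, the CD channel of a spectropolarimeter export) when the
    header does not name one.
    """
    if dialect not in ("csv", "jasco_text"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    header: dict[str, str] = {}
    wl: list[float] = []
    vals: list[float] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                header[key.strip()] = val.strip()
            continue
        fields = line.replace("\t", ",").split(",")
        fields = [f for f in (f.strip() for f in fields) if f]
        if len(fields) != 2:
            raise SpectrumParseError(
                f"{path.name}:{lineno}: expected two columns, got {len(fields)}"
            )
        try:
            wl.append(float(fields[0]))
            vals.append(float(fields[1]))
        except ValueError as exc:
            raise SpectrumParseError(
                f"{path.name}:{lineno}: non-numeric row {line!r}"
            ) from exc
    if not wl:
        raise SpectrumParseError(f"{path.name}: no data rows")
    wl_arr = np.array(wl)
    val_arr = np.array(vals)
    order = np.argsort(wl_arr, kind="stable")
    wl_arr, val_arr = wl_arr[order], val_arr[order]
    if wl_arr.size > 1 and np.any(np.diff(wl_arr) == 0):
        raise SpectrumParseError(f"{path.name}: duplicate wavelengths")

    default_unit = Unit.ELLIPTICITY_MDEG if dialect == "jasco_text" else Unit.DELTA_ABSORBANCE
    unit = Unit(header["unit"]) if "unit" in header else default_unit
    pathlength = float(header["pathlength_cm"]) if "pathlength_cm" in header else None
    meta = {k: v for k, v in header.items() if k not in ("unit", "pathlength_cm")}
    return Spectrum(wl_arr, val_arr, unit, pathlength, meta)


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    """Write a spectrum in the csv dialect; round-trips bitwise via repr."""
    path = Path(path)
    lines = [f"# unit: {s.unit.value}"]
    if s.pathlength_cm is not None:
        lines.append(f"# pathlength_cm: {s.pathlength_cm!r}")
    for key, val in s.meta.items():
        lines.append(f"# {key}: {val}")
    for wl, v in zip(s.wavelengths, s.values):
        lines.append(f"{float(wl)!r},{float(v)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_manifest(path: str | Path, dialect: str = "csv") -> TitrationSeries:
    """Read a titration manifest (JSON) into a :class:`TitrationSeries`.

    The manifest lists one entry per titration point::

        {"points": [{"file": "p0.csv", "guest_M": 4e-4,
                     "host_M": 0.0, "pathlength_cm": 1.0}, ...]}

    Relative file paths are resolved against the manifest's directory.
    """
    path = Path(path)
    doc = json.loads(path.read_text(encoding="utf-8"))
    points = []
    for entry in doc["points"]:
        spec_path = Path(entry["file"])
        if not spec_path.is_absolute():
            spec_path = path.parent / spec_path
        sol = SolutionSpec(
            guest_total=float(entry["guest_M"]),
            host_total=float(entry["host_M"]),
            pathlength_cm=float(entry.get("pathlength_cm", 1.0)),
        )
        points.append((sol, read_spectrum(spec_path, dialect=dialect)))
    return TitrationSeries(points)


def write_manifest(
    series: TitrationSeries, out_dir: str | Path, stem: str = "point"
) -> Path:
    """Write per-point spectrum files plus a manifest JSON; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (sol, spec) in enumerate(series):
        fname = f"{stem}{i:02d}.csv"
        write_spectrum(spec, out_dir / fname)
        entries.append(
            {
                "file": fname,
                "guest_M": sol.guest_total,
                "host_M": sol.host_total,
                "pathlength_cm": sol.pathlength_cm,
            }
        )
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps({"points": entries}, indent=1), encoding="utf-8")
    return manifest


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------

def _to_canonical(values: np.ndarray, unit: Unit, c: float | None, l: float | None):
    """Convert to the family's canonical unit (ΔA for CD, A for absorption)."""
    if unit in (Unit.DELTA_ABSORBANCE, Unit.ABSORBANCE):
        return values
    if unit is Unit.ELLIPTICITY_MDEG:
        return values / MDEG_PER_DELTA_A
    # molar units need c and l
    if c is None or l is None or c <= 0 or l <= 0:
        raise ValueError(
            "conversion of a molar unit requires positive guest concentration "
            "and pathlength"
        )
    return values * c * l


def _from_canonical(values: np.ndarray, unit: Unit, c: float | None, l: float | None):
    if unit in (Unit.DELTA_ABSORBANCE, Unit.ABSORBANCE):
        return values
    if unit is Unit.ELLIPTICITY_MDEG:
        return values * MDEG_PER_DELTA_A
    if c is None or l is None or c <= 0 or l <= 0:
        raise ValueError(
            "conversion to a molar unit requires positive guest concentration "
            "and pathlength"
        )
    return values / (c * l)


def convert_units(
    s: Spectrum,
    target_unit: Unit | str,
    solution: SolutionSpec | None = None,
) -> Spectrum:
    """Convert a spectrum between units of its family.

    CD units (mdeg, ΔA, Δε) interconvert via θ[mdeg] = 32982·ΔA and Beer's
    law ΔA = Δε·c·l; absorption units (A, ε) via A = ε·c·l.  Converting
    across the two families raises.  Concentration c is the total guest
    concentration of ``solution``; pathlength comes from ``solution`` or
    from the spectrum itself.
    """
    target = Unit(target_unit)
    if target.is_cd != s.unit.is_cd:
        raise ValueError(f"unsupported conversion {s.unit.value} -> {target.value}")
    if target is s.unit:
        return s.with_values(s.values.copy())
    c = solution.guest_total if solution is not None else None
    l = (
        solution.pathlength_cm
        if solution is not None
        else s.pathlength_cm
    )
    canonical = _to_canonical(s.values, s.unit, c, l)
    out = _from_canonical(canonical, target, c, l)
    return s.with_values(out, unit=target)


def subtract_blank(s: Spectrum, blank: Spectrum) -> Spectrum:
    """Subtract a blank spectrum measured on the same grid and unit."""
    if blank.unit is not s.unit:
        raise ValueError("blank unit does not match spectrum unit")
    if not np.array_equal(blank.wavelengths, s.wavelengths):
        raise ValueError("blank grid does not match spectrum grid")
    return s.with_values(s.values - blank.values)


# ---------------------------------------------------------------------------
# smoothing and peak readout
# ---------------------------------------------------------------------------

def fft_lowpass(
    s: Spectrum,
    cutoff_fraction: float = DEFAULT_CUTOFF_FRACTION,
    resample: bool = False,
) -> Spectrum:
    """Low-pass filter a spectrum by zeroing high Fourier components.

    Components above ``cutoff_fraction`` × Nyquist are zeroed; the DC term
    (signal mean) is always kept, so the filter is idempotent and
    mean-preserving.  The grid must be uniform; with ``resample=True`` a
    non-uniform grid is first linearly resampled to its median step (an
    explicit opt-in: silent interpolation is never performed).
    """
    if not 0 < cutoff_fraction <= 1:
        raise ValueError("cutoff_fraction must be in (0, 1]")
    if len(s) < 2:
        raise ValueError("need at least 2 points to filter")
    spec = s
    if not s.is_uniform():
        if not resample:
            raise ValueError(
                "non-uniform wavelength grid; pass resample=True to "
                "linearly resample to the median step"
            )
        step = float(np.median(np.diff(s.wavelengths)))
        n = max(int(round((s.wavelengths[-1] - s.wavelengths[0]) / step)) + 1, 2)
        grid = np.linspace(s.wavelengths[0], s.wavelengths[-1], n)
        spec = Spectrum(
            grid, np.interp(grid, s.wavelengths, s.values),
            s.unit, s.pathlength_cm, dict(s.meta),
        )

    n = len(spec)
    step = float(spec.wavelengths[1] - spec.wavelengths[0])
    coeffs = np.fft.rfft(spec.values)
    freqs = np.fft.rfftfreq(n, d=step)
    nyquist = 0.5 / step
    keep = freqs <= cutoff_fraction * nyquist
    keep[0] = True  # always keep the mean
    coeffs[~keep] = 0.0
    filtered = np.fft.irfft(coeffs, n=n)
    return spec.with_values(filtered)


@dataclass(frozen=True)
class PeakLocation:
    """A band-maximum readout with sub-grid precision.

    ``at_edge`` flags a maximum on the window boundary, where the quadratic
    refinement is undefined and the position is untrustworthy.
    """

    wavelength: float
    value: float
    at_edge: bool = False

    def __float__(self) -> float:
        return self.wavelength


def find_lambda_max(
    s: Spectrum, window: tuple[float, float] | None = None
) -> PeakLocation:
    """Locate the band maximum, refined by a local quadratic fit.

    The grid maximum within ``window`` and its two neighbours define a
    parabola whose vertex gives sub-grid-step precision.  Ties break toward
    the lower wavelength; a maximum on the window edge is flagged.
    """
    wl, vals = s.wavelengths, s.values
    if window is not None:
        lo, hi = window
        mask = (wl >= lo) & (wl <= hi)
        if not mask.any():
            raise ValueError("window does not overlap the wavelength grid")
        idx = np.flatnonzero(mask)
    else:
        idx = np.arange(len(wl))
    sub_vals = vals[idx]
    k = int(np.argmax(sub_vals))  # first occurrence -> lower wavelength
    i = int(idx[k])
    if k == 0 or k == len(idx) - 1:
        return PeakLocation(float(wl[i]), float(vals[i]), at_edge=True)
    x0, x1, x2 = wl[i - 1], wl[i], wl[i + 1]
    y0, y1, y2 = vals[i - 1], vals[i], vals[i + 1]
    denom = (x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0)
    if denom == 0:  # locally flat triple
        return PeakLocation(float(x1), float(y1))
    vertex = x1 - 0.5 * (
        (x1 - x0) ** 2 * (y1 - y2) - (x1 - x2) ** 2 * (y1 - y0)
    ) / denom
    a = np.polyfit([x0, x1, x2], [y0, y1, y2], 2)
    peak_val = float(np.polyval(a, vertex))
    return PeakLocation(float(vertex), peak_val)
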