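"""Cyclodextrin cavity frames and ICD sign prediction.

The seven glycosidic (O4) bridge oxygens of β-cyclodextrin form the most
rigid ring of the macrocycle; their least-squares plane defines the cavity
axis, oriented from the narrow (primary, O6) rim toward the wide (secondary,
O2/O3) rim.  Given a guest chromophore position and its electronic
transition dipole moment in the same coordinate frame, the Kodaka–Harata
rules predict the sign of the induced CD band:

* chromophore inside the cavity, dipole parallel to the axis  -> positive
* chromophore inside the cavity, dipole perpendicular         -> negative
* chromophore outside the cavity: both signs reverse.

"Parallel" and "perpendicular" are operationalised by the orientation
factor (3·cos²θ − 1)/2, which changes sign at the magic angle
θ_m = 54.7356°; angles within ``magic_tol`` of θ_m are indeterminate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "MAGIC_ANGLE_DEG",
    "Atom",
    "HostGeometry",
    "CavityFrame",
    "TransitionDipole",
    "SignPrediction",
    "parse_structure",
    "fit_cavity_axis",
    "classify_position",
    "dipole_angle",
    "dipole_magnitude",
    "orientation_factor",
    "kodaka_harata_sign",
    "predict_complex_sign",
]

#: Angle at which 3cos²θ − 1 = 0; the parallel/perpendicular crossover.
MAGIC_ANGLE_DEG = math.degrees(math.acos(1.0 / math.sqrt(3.0)))  # 54.7356...

DEFAULT_HALF_HEIGHT = 4.0     # Å, half the usable cavity depth of β-CyD
DEFAULT_RADIAL_MARGIN = 1.0   # × O4 ring radius
DEFAULT_MAGIC_TOL = 5.0       # degrees


@dataclass(frozen=True)
class Atom:
    name: str
    res_index: int
    res_name: str
    xyz: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "xyz", np.asarray(self.xyz, dtype=float))
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: invalid coordinates")


def _normalize_name(name: str) -> str:
    return name.upper().replace("'", "").replace("*", "").strip()


def _classify_oxygen(name: str) -> str | None:
    """Map an atom name to its rim role: O4 (glycosidic), O6, or O2/O3."""
    n = _normalize_name(name)
    if n.startswith("O4"):
        return "O4"
    if n.startswith("O6"):
        return "O6"
    if n.startswith("O2") or n.startswith("O3"):
        return "O23"
    return None


@dataclass
class HostGeometry:
    """Cyclodextrin host atoms with the three oxygen-ring selections."""

    atoms: list[Atom]
    selections: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if not self.selections:
            sel: dict[str, list[np.ndarray]] = {"O4": [], "O6": [], "O23": []}
            for atom in self.atoms:
                role = _classify_oxygen(atom.name)
                if role is not None:
                    sel[role].append(atom.xyz)
            self.selections = {
                k: (np.vstack(v) if v else np.empty((0, 3))) for k, v in sel.items()
            }

    @property
    def glycosidic_oxygens(self) -> np.ndarray:
        return self.selections.get("O4", np.empty((0, 3)))


@dataclass(frozen=True)
class CavityFrame:
    """The cavity coordinate frame derived from the glycosidic-oxygen ring.

    ``origin`` is the O4 centroid, ``axis`` the unit normal of the O4
    least-squares plane oriented narrow→wide rim (``oriented`` is False when
    no rim oxygens were available to fix the sign), ``ring_radius`` the mean
    O4 distance from the axis, and ``planarity_rms`` the RMS out-of-plane
    deviation of the O4 ring — a validity diagnostic for the planar-ring
    assumption.
    """

    origin: np.ndarray
    axis: np.ndarray
    ring_radius: float
    planarity_rms: float
    oriented: bool = True

    def axial_radial(self, point) -> tuple[float, float]:
        """Axial and radial cylindrical coordinates of a point in this frame."""
        rel = np.asarray(point, dtype=float) - self.origin
        z = float(rel @ self.axis)
        r = float(np.linalg.norm(rel - z * self.axis))
        return z, r


@dataclass(frozen=True)
class TransitionDipole:
    """An electronic transition dipole moment vector in Debye."""

    components: np.ndarray

    def __post_init__(self):
        comp = np.asarray(self.components, dtype=float)
        if comp.shape != (3,) or not np.all(np.isfinite(comp)):
            raise ValueError("dipole needs 3 finite components")
        object.__setattr__(self, "components", comp)

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.components))


@dataclass(frozen=True)
class SignPrediction:
    """Outcome of the sign rules, with full provenance."""

    location: str                  # "inside" | "outside"
    theta_deg: float               # dipole-axis angle, [0, 90]
    orientation_factor: float      # (3cos²θ − 1)/2
    predicted_sign: str            # "positive" | "negative" | "indeterminate"
    frame: CavityFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "location": self.location,
            "theta_deg": self.theta_deg,
            "orientation_factor": self.orientation_factor,
            "predicted_sign": self.predicted_sign,
        }
        if self.frame is not None:
            d["frame"] = {
                "origin": self.frame.origin.tolist(),
                "axis": self.frame.axis.tolist(),
                "ring_radius": self.frame.ring_radius,
                "planarity_rms": self.frame.planarity_rms,
                "oriented": self.frame.oriented,
            }
        return d


# ---------------------------------------------------------------------------
# structure parsing
# ---------------------------------------------------------------------------

def _parse_pdb(path: Path) -> list[Atom]:
    import gemmi

    structure = gemmi.read_pdb(str(path))
    atoms: list[Atom] = []
    idx = 0
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    atoms.append(
                        Atom(
                            name=atom.name,
                            res_index=idx,
                            res_name=residue.name.strip(),
                            xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        )
                    )
                idx += 1
        break  # first model only
    return atoms


def _parse_xyz(path: Path) -> list[Atom]:
    lines = path.read_text(encoding="utf-8").splitlines()
    if len(lines) < 3:
        raise ValueError(f"{path.name}: not a valid XYZ file")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path.name}:1: expected atom count") from exc
    atoms = []
    for i, line in enumerate(lines[2 : 2 + natoms], start=3):
        fields = line.split()
        if len(fields) < 4:
            raise ValueError(f"{path.name}:{i}: malformed XYZ record")
        try:
            xyz = np.array([float(v) for v in fields[1:4]])
        except ValueError as exc:
            raise ValueError(f"{path.name}:{i}: non-numeric coordinates") from exc
        atoms.append(Atom(name=fields[0], res_index=0, res_name="XYZ", xyz=xyz))
    if len(atoms) != natoms:
        raise ValueError(f"{path.name}: expected {natoms} atoms, found {len(atoms)}")
    return atoms


def parse_structure(
    path,
    host_selector: Sequence[str] | Sequence[int] | None = None,
    guest_selector: Sequence[str] | Sequence[int] | None = None,
) -> tuple[HostGeometry, list[Atom]]:
    """Read a PDB or XYZ structure and split it into host and guest.

    For PDB input the selectors are residue names (e.g. ``["LIG"]`` for the
    guest); atoms in guest residues form the guest set and everything else
    the host.  XYZ files carry no residue labels, so there the selectors are
    0-based atom-index collections.  Oxygen ring selections (glycosidic O4,
    primary-rim O6, secondary-rim O2/O3) are matched case-insensitively with
    primes/asterisks stripped, so O4, O44 and O4' dialects all match.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".xyz":
        atoms = _parse_xyz(path)
        guest_idx = set(int(i) for i in (guest_selector or []))
        host_idx = (
            set(int(i) for i in host_selector)
            if host_selector is not None
            else set(range(len(atoms))) - guest_idx
        )
        host_atoms = [a for i, a in enumerate(atoms) if i in host_idx]
        guest_atoms = [a for i, a in enumerate(atoms) if i in guest_idx]
    else:
        atoms = _parse_pdb(path)
        guest_names = {str(n).upper() for n in (guest_selector or [])}
        host_names = (
            {str(n).upper() for n in host_selector} if host_selector else None
        )
        guest_atoms = [a for a in atoms if a.res_name.upper() in guest_names]
        if host_names is not None:
            host_atoms = [a for a in atoms if a.res_name.upper() in host_names]
        else:
            host_atoms = [a for a in atoms if a.res_name.upper() not in guest_names]

    host = HostGeometry(host_atoms)
    n_gly = len(host.glycosidic_oxygens)
    if n_gly < 3:
        available = sorted({a.name for a in host_atoms})
        raise ValueError(
            f"found only {n_gly} glycosidic (O4) oxygens in the host "
            f"(need >= 3); atom names present: {available}"
        )
    if guest_selector and not guest_atoms:
        import warnings

        warnings.warn(
            f"guest selector {guest_selector!r} matched no atoms", stacklevel=2
        )
    return host, guest_atoms


# ---------------------------------------------------------------------------
# frame fitting and the sign rules
# ---------------------------------------------------------------------------

def fit_cavity_axis(host: HostGeometry) -> CavityFrame:
    """Fit the cavity frame to the glycosidic-oxygen ring.

    The axis is the unit normal of the least-squares plane through the O4
    atoms (smallest principal direction of the centred scatter), with its
    sign fixed so the secondary-rim (wide, O2/O3) centroid lies at positive
    axial coordinate; the O6 (narrow) centroid is used with opposite sense
    if only the primary rim is present.
    """
    O4 = host.glycosidic_oxygens
    if len(O4) < 3:
        raise ValueError("need at least 3 glycosidic oxygens to fit the axis")
    origin = O4.mean(axis=0)
    centred = O4 - origin
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    if svals[1] < 1e-10 * max(svals[0], 1.0):
        raise ValueError("glycosidic oxygens are collinear; no plane defined")
    axis = vt[2]

    oriented = True
    O23 = host.selections.get("O23", np.empty((0, 3)))
    O6 = host.selections.get("O6", np.empty((0, 3)))
    if len(O23) > 0:
        if (O23.mean(axis=0) - origin) @ axis < 0:
            axis = -axis
    elif len(O6) > 0:
        if (O6.mean(axis=0) - origin) @ axis > 0:
            axis = -axis
    else:
        oriented = False

    axial = centred @ axis
    radial = np.linalg.norm(centred - np.outer(axial, axis), axis=1)
    return CavityFrame(
        origin=origin,
        axis=axis / np.linalg.norm(axis),
        ring_radius=float(radial.mean()),
        planarity_rms=float(np.sqrt(np.mean(axial**2))),
        oriented=oriented,
    )


def classify_position(
    centroid,
    frame: CavityFrame,
    half_height: float = DEFAULT_HALF_HEIGHT,
    radial_margin: float = DEFAULT_RADIAL_MARGIN,
) -> str:
    """Classify a chromophore centroid as inside or outside the cavity.

    Inside means within ``half_height`` Å of the O4 plane along the axis
    AND within ``radial_margin`` × ring radius of the axis; both boundaries
    are closed (a point exactly on the rim counts as inside).
    """
    z, r = frame.axial_radial(centroid)
    inside = abs(z) <= half_height and r <= radial_margin * frame.ring_radius
    return "inside" if inside else "outside"


def dipole_magnitude(components) -> float:
    """Euclidean norm of a dipole's Cartesian components (Debye)."""
    comp = np.asarray(components, dtype=float)
    if not np.all(np.isfinite(comp)):
        raise ValueError("dipole components must be finite")
    return float(np.linalg.norm(comp))


def dipole_angle(dipole: TransitionDipole, frame: CavityFrame) -> float:
    """Angle (degrees, folded to [0, 90]) between dipole and cavity axis.

    A transition dipole has no physical sign, so the angle is computed from
    the absolute projection.
    """
    mag = dipole.magnitude
    if mag == 0:
        raise ValueError("zero dipole vector has no direction")
    cos_t = abs(float(dipole.components @ frame.axis)) / mag
    return math.degrees(math.acos(min(cos_t, 1.0)))


def orientation_factor(theta_deg: float) -> float:
    """(3·cos²θ − 1)/2: +1 parallel, −1/2 perpendicular, 0 at the magic angle."""
    c = math.cos(math.radians(theta_deg))
    return (3.0 * c * c - 1.0) / 2.0


def kodaka_harata_sign(
    location: str,
    theta_deg: float,
    magic_tol: float = DEFAULT_MAGIC_TOL,
    frame: CavityFrame | None = None,
) -> SignPrediction:
    """Apply the sign rules for an induced CD band.

    Inside the cavity a dipole more axial than the magic angle gives a
    positive band and a more equatorial one a negative band; outside the
    cavity both reverse.  Within ``magic_tol`` degrees of the magic angle
    the orientation factor is too close to zero to call a sign.
    """
    if location not in ("inside", "outside"):
        raise ValueError("location must be 'inside' or 'outside'")
    if not 0.0 <= theta_deg <= 90.0:
        raise ValueError("theta must be in [0, 90] degrees")
    factor = orientation_factor(theta_deg)
    if abs(theta_deg - MAGIC_ANGLE_DEG) <= magic_tol:
        sign = "indeterminate"
    else:
        axial_like = theta_deg < MAGIC_ANGLE_DEG
        if location == "inside":
            sign = "positive" if axial_like else "negative"
        else:
            sign = "negative" if axial_like else "positive"
    return SignPrediction(
        location=location,
        theta_deg=theta_deg,
        orientation_factor=factor,
        predicted_sign=sign,
        frame=frame,
    )


def predict_complex_sign(
    structure,
    dipole: TransitionDipole,
    guest_selector: Sequence[str] | Sequence[int] | None = None,
    host_selector: Sequence[str] | Sequence[int] | None = None,
    half_height: float = DEFAULT_HALF_HEIGHT,
    radial_margin: float = DEFAULT_RADIAL_MARGIN,
    magic_tol: float = DEFAULT_MAGIC_TOL,
    chromophore_centroid=None,
) -> SignPrediction:
    """End-to-end ICD sign prediction for a complex structure.

    ``structure`` is a PDB/XYZ path or a pre-parsed
    ``(HostGeometry, guest_atoms)`` pair.  The dipole vector and the
    structure must share one coordinate frame — this function never guesses
    a frame transformation.  The chromophore centroid defaults to the mean
    of the guest atoms; pass ``chromophore_centroid`` to use a subset
    (e.g. a single ring) selected upstream.
    """
    if isinstance(structure, (str, Path)):
        host, guest_atoms = parse_structure(
            structure, host_selector=host_selector, guest_selector=guest_selector
        )
    else:
        host, guest_atoms = structure
    frame = fit_cavity_axis(host)
    if chromophore_centroid is None:
        if not guest_atoms:
            raise ValueError("no guest atoms to locate the chromophore")
        chromophore_centroid = np.mean([a.xyz for a in guest_atoms], axis=0)
    location = classify_position(
        chromophore_centroid, frame, half_height=half_height,
        radial_margin=radial_margin,
    )
    theta = dipole_angle(dipole, frame)
    return kodaka_harata_sign(location, theta, magic_tol=magic_tol, frame=frame)
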