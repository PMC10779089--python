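"""Synthetic titrations and toy complex geometries.

The generator stands in for the spectrometer and for MD/QM outputs: it
produces CD/UV titration series from the same 1:1 equilibrium and Gaussian
band shapes the analysis assumes, and toy cyclodextrin geometries (rings of
rim-marker oxygens plus a placeable guest chromophore with a transition
dipole) on which the frame fitting and sign rules can be exercised without
any external structure files.

The built-in scenario mirrors a fenoprofen-like experiment: guest total
0.4 mM in a 1.0 cm cell at host:guest ratios 0/5/20, a free UV band at
270.6 nm with a ~3 nm bathochromic and hyperchromic shift on complexation,
structured (two-band) complex CD near 274.6/280.6 nm, and log10 K = 3.06.
A nimesulide-like scenario (391.4 nm band, ~10 nm shift, ratios 0/5/25/30)
is provided as the large-shift counterpart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .binding import icd_response, speciate, uv_mixture
from .geometry import Atom, HostGeometry, TransitionDipole
from .spectra import SolutionSpec, Spectrum, TitrationSeries, Unit

__all__ = [
    "BandSpec",
    "ScenarioSpec",
    "SyntheticTitration",
    "fenoprofen_like",
    "nimesulide_like",
    "generate_titration",
    "generate_toy_cyclodextrin",
    "generate_guest",
    "write_pdb",
]


@dataclass(frozen=True)
class BandSpec:
    """A Gaussian spectral band: centre (nm), σ width (nm), peak amplitude.

    Amplitudes are in molar units (ε or Δε, M⁻¹cm⁻¹); CD amplitudes may be
    negative.
    """

    center: float
    width: float
    amplitude: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if not math.isfinite(self.amplitude):
            raise ValueError("band amplitude must be finite")

    def __call__(self, wavelengths: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(
            -0.5 * ((wavelengths - self.center) / self.width) ** 2
        )


def _band_sum(bands, wavelengths: np.ndarray) -> np.ndarray:
    out = np.zeros_like(wavelengths, dtype=float)
    for b in bands:
        out += b(wavelengths)
    return out


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of a synthetic titration experiment.

    ``noise_sigma_cd``/``noise_sigma_uv`` are absolute Gaussian standard
    deviations in the output units (ΔA and A); a seed is mandatory whenever
    either is non-zero, so every noisy realisation is reproducible.
    """

    true_logK: float = 3.06
    guest_total: float = 4e-4
    host_ratios: tuple[float, ...] = (0.0, 5.0, 20.0)
    pathlength_cm: float = 1.0
    wl_start: float = 240.0
    wl_stop: float = 320.0
    wl_step: float = 0.5
    free_uv_bands: tuple[BandSpec, ...] = (BandSpec(270.6, 7.0, 1400.0),)
    complex_uv_bands: tuple[BandSpec, ...] = (BandSpec(273.5, 7.0, 1700.0),)
    complex_cd_bands: tuple[BandSpec, ...] = (
        BandSpec(274.6, 2.5, 1.6),
        BandSpec(280.6, 2.5, 2.0),
    )
    noise_sigma_cd: float = 0.0
    noise_sigma_uv: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if any(r < 0 for r in self.host_ratios):
            raise ValueError("host ratios must be non-negative")
        if self.guest_total <= 0:
            raise ValueError("guest_total must be positive")
        if (self.noise_sigma_cd > 0 or self.noise_sigma_uv > 0) and self.seed is None:
            raise ValueError("a seed is required for noisy output")

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.wl_stop - self.wl_start) / self.wl_step)) + 1
        return self.wl_start + self.wl_step * np.arange(n)

    @property
    def K(self) -> float:
        return 10.0 ** self.true_logK


def fenoprofen_like(
    noise_fraction: float = 0.0, seed: int | None = None, **overrides
) -> ScenarioSpec:
    """The default fenoprofen-like scenario, optionally with relative noise.

    ``noise_fraction`` is converted to absolute σ as a fraction of the
    noise-free peak |signal| of the most saturated point, separately for the
    CD and UV channels.
    """
    spec = ScenarioSpec(seed=seed, **overrides)
    if noise_fraction > 0:
        spec = _with_relative_noise(spec, noise_fraction, seed)
    return spec


def nimesulide_like(
    noise_fraction: float = 0.0, seed: int | None = None, **overrides
) -> ScenarioSpec:
    """A nimesulide-like scenario: 391.4 nm band, ~10 nm shift, ratios to 30×."""
    defaults = dict(
        guest_total=2e-4,
        host_ratios=(0.0, 5.0, 25.0, 30.0),
        wl_start=330.0,
        wl_stop=460.0,
        free_uv_bands=(BandSpec(391.4, 16.0, 5000.0),),
        complex_uv_bands=(BandSpec(401.0, 16.0, 6500.0),),
        complex_cd_bands=(BandSpec(391.4, 14.0, 3.0),),
    )
    defaults.update(overrides)
    spec = ScenarioSpec(seed=seed, **defaults)
    if noise_fraction > 0:
        spec = _with_relative_noise(spec, noise_fraction, seed)
    return spec


def _with_relative_noise(
    spec: ScenarioSpec, fraction: float, seed: int | None
) -> ScenarioSpec:
    if seed is None:
        raise ValueError("a seed is required for noisy output")
    clean = generate_titration(replace(spec, noise_sigma_cd=0.0,
                                       noise_sigma_uv=0.0, seed=seed))
    peak_cd = max(np.max(np.abs(s.values)) for _, s in clean.cd)
    peak_uv = max(np.max(np.abs(s.values)) for _, s in clean.uv)
    return replace(
        spec,
        noise_sigma_cd=fraction * peak_cd,
        noise_sigma_uv=fraction * peak_uv,
        seed=seed,
    )


@dataclass
class SyntheticTitration:
    """Generated CD and UV titration series plus the generating truth."""

    cd: TitrationSeries
    uv: TitrationSeries
    scenario: ScenarioSpec

    @property
    def true_delta_eps(self) -> Spectrum:
        """The generating complex CD band (Δε_complex) on the scenario grid."""
        wl = self.scenario.wavelengths
        return Spectrum(
            wl, _band_sum(self.scenario.complex_cd_bands, wl), Unit.DELTA_EPSILON
        )


def generate_titration(spec: ScenarioSpec) -> SyntheticTitration:
    """Generate a CD + UV titration series from a scenario.

    For each host ratio the 1:1 speciation is solved at the scenario's K;
    the CD point is the complex-only response Δε_c·[complex]·l and the UV
    point the free/complex absorbance mixture; seeded Gaussian noise is
    added last.  All concentrations and pathlengths are embedded in the
    points so the fitters can run blind.
    """
    wl = spec.wavelengths
    deps_c = Spectrum(wl, _band_sum(spec.complex_cd_bands, wl), Unit.DELTA_EPSILON)
    eps_f = Spectrum(wl, _band_sum(spec.free_uv_bands, wl), Unit.MOLAR_ABSORPTION)
    eps_c = Spectrum(wl, _band_sum(spec.complex_uv_bands, wl), Unit.MOLAR_ABSORPTION)

    rng = np.random.default_rng(spec.seed) if spec.seed is not None else None
    cd_points, uv_points = [], []
    for ratio in spec.host_ratios:
        H = ratio * spec.guest_total
        sol = SolutionSpec(spec.guest_total, H, spec.pathlength_cm)
        species = speciate(spec.guest_total, H, spec.K)
        cd = icd_response(deps_c, species, spec.pathlength_cm)
        uv = uv_mixture(eps_f, eps_c, species, spec.pathlength_cm)
        if rng is not None and spec.noise_sigma_cd > 0:
            cd = cd.with_values(cd.values + rng.normal(0, spec.noise_sigma_cd, wl.size))
        if rng is not None and spec.noise_sigma_uv > 0:
            uv = uv.with_values(uv.values + rng.normal(0, spec.noise_sigma_uv, wl.size))
        meta = {"host_ratio": ratio, "true_logK": spec.true_logK}
        cd = Spectrum(wl, cd.values, cd.unit, spec.pathlength_cm, meta)
        uv = Spectrum(wl, uv.values, uv.unit, spec.pathlength_cm, dict(meta))
        cd_points.append((sol, cd))
        uv_points.append((sol, uv))
    return SyntheticTitration(
        cd=TitrationSeries(cd_points), uv=TitrationSeries(uv_points), scenario=spec
    )


# ---------------------------------------------------------------------------
# toy geometries
# ---------------------------------------------------------------------------

def generate_toy_cyclodextrin(
    n_units: int = 7,
    ring_radius: float = 5.0,
    rim_offset: float = 2.0,
    jitter: float = 0.0,
    seed: int | None = None,
) -> HostGeometry:
    """Build an idealised cyclodextrin oxygen scaffold.

    ``n_units`` glucose units contribute one glycosidic O4 each, equally
    spaced on a circle of ``ring_radius`` Å at z = 0; the primary-rim O6
    ring sits at z = −``rim_offset`` with a smaller radius (narrow rim) and
    the secondary-rim O2/O3 oxygens at z = +``rim_offset`` with a larger
    radius (wide rim), so the fitted axis points along +z.  Optional
    Gaussian coordinate jitter (seeded) emulates conformational disorder.
    """
    if n_units < 3:
        raise ValueError("need at least 3 glucose units")
    rng = np.random.default_rng(seed)
    angles = 2.0 * np.pi * np.arange(n_units) / n_units
    atoms: list[Atom] = []

    def ring(name: str, radius: float, z: float, phase: float = 0.0):
        for i, a in enumerate(angles):
            xyz = np.array(
                [radius * np.cos(a + phase), radius * np.sin(a + phase), z]
            )
            if jitter > 0:
                xyz = xyz + rng.normal(0.0, jitter, 3)
            atoms.append(Atom(name=name, res_index=i, res_name="GLC", xyz=xyz))

    ring("O4", ring_radius, 0.0)
    ring("O6", 0.8 * ring_radius, -rim_offset)
    ring("O2", 1.2 * ring_radius, +rim_offset, phase=-0.15)
    ring("O3", 1.2 * ring_radius, +rim_offset, phase=+0.15)
    atoms.sort(key=lambda at: at.res_index)
    return HostGeometry(atoms)


def generate_guest(
    position=(0.0, 0.0, 0.0),
    dipole_theta: float = 0.0,
    magnitude: float = 1.0,
    res_name: str = "LIG",
) -> tuple[list[Atom], TransitionDipole]:
    """A minimal rigid chromophore with a dipole at a set angle to +z.

    Three collinear carbon placeholders (1.4 Å spacing, along the dipole
    direction) centred at ``position``; the dipole lies in the xz-plane at
    ``dipole_theta`` degrees from the +z cavity axis.
    """
    if magnitude <= 0:
        raise ValueError("dipole magnitude must be positive")
    pos = np.asarray(position, dtype=float)
    t = math.radians(dipole_theta)
    direction = np.array([math.sin(t), 0.0, math.cos(t)])
    dipole = TransitionDipole(magnitude * direction)
    atoms = [
        Atom(name=f"C{i + 1}", res_index=999, res_name=res_name,
             xyz=pos + (i - 1) * 1.4 * direction)
        for i in range(3)
    ]
    return atoms, dipole


def write_pdb(path, host: HostGeometry, guest_atoms=None) -> None:
    """Write host (chain A) and optional guest (chain B) as a PDB file."""
    import gemmi

    structure = gemmi.Structure()
    structure.name = "toy_complex"
    model = gemmi.Model("1")

    def add_chain(name: str, atom_list):
        chain = gemmi.Chain(name)
        residues: dict[int, gemmi.Residue] = {}
        for at in atom_list:
            res = residues.get(at.res_index)
            if res is None:
                res = gemmi.Residue()
                res.name = at.res_name
                res.seqid = gemmi.SeqId(at.res_index + 1, " ")
                res.het_flag = "H"
                residues[at.res_index] = res
            a = gemmi.Atom()
            a.name = at.name
            a.element = gemmi.Element(at.name[0])
            a.pos = gemmi.Position(*at.xyz)
            res.add_atom(a)
        for key in sorted(residues):
            chain.add_residue(residues[key])
        model.add_chain(chain)

    add_chain("A", host.atoms)
    if guest_atoms:
        add_chain("B", guest_atoms)
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))
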