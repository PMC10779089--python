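"""Reference transition dipole moments for four drug–β-cyclodextrin systems.

TDDFT-derived Cartesian components (Debye) of the lowest relevant electronic
transition dipole for each guest free in water and in its β-cyclodextrin
complex, together with the published total magnitude.  These serve as worked
examples for :func:`icdbind.geometry.dipole_magnitude` and as a consistency
check: the Euclidean norm of the components must reproduce the quoted total.

The components are given in the lab frame of the underlying excited-state
calculation, which is not the cavity frame; they therefore support magnitude
checks but not, by themselves, dipole–axis angle computations.
"""

from __future__ import annotations

__all__ = ["REFERENCE_TRANSITION_DIPOLES"]

#: name -> ((x, y, z) in Debye, quoted total magnitude in Debye)
REFERENCE_TRANSITION_DIPOLES: dict[str, tuple[tuple[float, float, float], float]] = {
    "fenoprofen (water)": ((0.0917, -0.5624, -0.4419), 0.7211),
    "fenoprofen-BCyD": ((-0.0456, -0.0700, 0.1518), 0.1732),
    "fenbufen (water)": ((-0.9793, -0.8206, -0.4739), 1.3627),
    "fenbufen-BCyD": ((0.0105, -0.1213, 0.2067), 0.2398),
    "nimesulide (water)": ((0.5110, 0.2802, 0.2288), 0.6261),
    "nimesulide-BCyD": ((-0.5166, -0.3848, -1.3888), 1.5309),
    "bifonazole (water)": ((-0.3578, -0.2423, -0.0594), 0.4361),
    "bifonazole-BCyD biphenyl in ring": ((-0.0514, 0.7572, -0.7827), 1.0902),
    "bifonazole-BCyD phenyl in ring": ((-1.3510, 1.9622, -3.2134), 4.0002),
}
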