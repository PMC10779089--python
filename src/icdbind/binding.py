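"""1:1 host–guest binding: speciation, spectral models and K fitting.

The chemistry is the mass-action equilibrium

    host + guest  <=>  complex,      K = [complex] / ([host][guest])

with totals G (guest) and H (host).  An induced-CD signal reports only the
complex (the free guest and the free cyclodextrin are CD-silent above
220 nm), so at any wavelength

    ΔA(λ) = Δε_complex(λ) · [complex] · l,

while the UV absorbance is the concentration-weighted mixture of the free
and complexed guest chromophore:

    A(λ) = (ε_free(λ)·[guest] + ε_complex(λ)·[complex]) · l.

:class:`IcdTitrationModel` fits K (on the log10 scale) to a titration series
either at a single wavelength or globally across the grid by variable
projection: for each trial K the per-wavelength complex coefficient
Δε_c(λ) has a closed-form linear least-squares solution, leaving a smooth
1-D problem in log10 K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .spectra import Spectrum, SolutionSpec, TitrationSeries, Unit, find_lambda_max

__all__ = [
    "SpeciesConcentrations",
    "speciate",
    "icd_response",
    "uv_mixture",
    "shift_curve",
    "IcdTitrationModel",
    "BindingFitResults",
]

LOGK_BOUNDS = (0.0, 6.0)
_LOGK_GRID_STEP = 0.05
#: Saturation-fraction range below which the curve carries little K information.
ILL_CONDITIONED_SATURATION_RANGE = 0.2


@dataclass(frozen=True)
class SpeciesConcentrations:
    """Equilibrium concentrations (molar) of the three species."""

    free_guest: float
    free_host: float
    complex: float

    @property
    def guest_total(self) -> float:
        return self.free_guest + self.complex

    @property
    def host_total(self) -> float:
        return self.free_host + self.complex


def speciate(guest_total: float, host_total: float, K: float) -> SpeciesConcentrations:
    """Solve the 1:1 equilibrium for the complex concentration.

    The physical root of K·(G−c)(H−c) = c is computed in the
    cancellation-safe form c = 2GH / (S + sqrt(S² − 4GH)) with
    S = G + H + 1/K, which avoids subtracting nearly equal numbers when
    binding is weak or one total dominates.
    """
    G, H = float(guest_total), float(host_total)
    if G < 0 or H < 0 or K < 0:
        raise ValueError("totals and K must be non-negative")
    if K == 0 or G == 0 or H == 0:
        return SpeciesConcentrations(G, H, 0.0)
    S = G + H + 1.0 / K
    disc = S * S - 4.0 * G * H
    c = 2.0 * G * H / (S + math.sqrt(max(disc, 0.0)))
    c = min(c, G, H)  # guard rounding at hard saturation
    return SpeciesConcentrations(G - c, H - c, c)


def _complex_dK(G: float, H: float, K: float, c: float) -> float:
    """d[complex]/dK from implicit differentiation of K(G−c)(H−c)=c."""
    g, h = G - c, H - c
    return g * h / (1.0 + K * (g + h))


def icd_response(
    delta_eps_complex: Spectrum,
    species: SpeciesConcentrations,
    pathlength_cm: float,
) -> Spectrum:
    """ICD spectrum of a solution: ΔA(λ) = Δε_complex(λ)·[complex]·l.

    Only the complex contributes — the band shape is fixed and the whole
    spectrum scales with the complex concentration, which is why the CD
    band maximum does not shift along a titration.
    """
    if pathlength_cm <= 0:
        raise ValueError("pathlength must be positive")
    values = delta_eps_complex.values * species.complex * pathlength_cm
    return delta_eps_complex.with_values(values, unit=Unit.DELTA_ABSORBANCE)


def uv_mixture(
    eps_free: Spectrum,
    eps_complex: Spectrum,
    species: SpeciesConcentrations,
    pathlength_cm: float,
) -> Spectrum:
    """UV absorbance of the free/complex mixture.

    A(λ) = (ε_free·[free guest] + ε_complex·[complex])·l: the apparent band
    drifts from the free-guest maximum toward the complex maximum as the
    complexed fraction grows.
    """
    if pathlength_cm <= 0:
        raise ValueError("pathlength must be positive")
    if not np.array_equal(eps_free.wavelengths, eps_complex.wavelengths):
        raise ValueError("component spectra are not on a common grid")
    values = (
        eps_free.values * species.free_guest
        + eps_complex.values * species.complex
    ) * pathlength_cm
    return eps_free.with_values(values, unit=Unit.ABSORBANCE)


def shift_curve(
    eps_free: Spectrum,
    eps_complex: Spectrum,
    K: float,
    guest_total: float,
    host_totals,
    pathlength_cm: float = 1.0,
    window: tuple[float, float] | None = None,
) -> list[tuple[float, float]]:
    """Apparent UV λmax as a function of total host concentration.

    For a red-shifted complex band the apparent maximum moves monotonically
    from the free-guest maximum (no host) toward the complex maximum
    (saturating host) — the bathochromic drift seen along a titration.
    """
    out = []
    for H in host_totals:
        sp = speciate(guest_total, H, K)
        mix = uv_mixture(eps_free, eps_complex, sp, pathlength_cm)
        out.append((float(H), find_lambda_max(mix, window).wavelength))
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class IcdTitrationModel:
    """1:1 binding model for an ICD titration series.

    Parameters
    ----------
    series : TitrationSeries
        Titration points (fixed guest total, varying host total).  Signals
        may be in any unit proportional to the complex concentration
        (ellipticity, ΔA, Δε·const); the fitted per-wavelength coefficient
        absorbs the proportionality and log10 K is invariant to it.

    Examples
    --------
    >>> model = IcdTitrationModel.from_manifest("series/manifest.json")
    >>> res = model.fit()              # global, all wavelengths
    >>> res = model.fit(wavelength=280.6)   # single-wavelength saturation curve
    >>> print(res.summary())
    """

    def __init__(self, series: TitrationSeries):
        if len(series) < 3:
            raise ValueError("need at least 3 titration points to fit K")
        if len(set(np.round(series.host_totals, 15))) < 2:
            raise ValueError("need at least 2 distinct host concentrations")
        self.series = series

    @classmethod
    def from_manifest(cls, path, dialect: str = "csv") -> "IcdTitrationModel":
        from .spectra import read_manifest

        return cls(read_manifest(path, dialect=dialect))

    # -- internal machinery -------------------------------------------------

    def _design(self, logK: float) -> np.ndarray:
        """x_i = [complex]_i · l_i for each titration point at trial K."""
        K = 10.0 ** logK
        G = self.series.guest_total
        return np.array(
            [
                speciate(G, sol.host_total, K).complex * sol.pathlength_cm
                for sol, _ in self.series
            ]
        )

    def _design_dlogK(self, logK: float) -> np.ndarray:
        K = 10.0 ** logK
        G = self.series.guest_total
        out = []
        for sol, _ in self.series:
            c = speciate(G, sol.host_total, K).complex
            out.append(_complex_dK(G, sol.host_total, K, c) * K * math.log(10.0)
                       * sol.pathlength_cm)
        return np.array(out)

    @staticmethod
    def _project(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, float]:
        """Closed-form Δε_c per wavelength and the residual sum of squares."""
        xx = float(x @ x)
        if xx == 0.0:
            return np.zeros(Y.shape[1]), float(np.sum(Y * Y))
        coeffs = (x @ Y) / xx
        resid = Y - np.outer(x, coeffs)
        return coeffs, float(np.sum(resid * resid))

    def _optimize_logK(self, Y: np.ndarray) -> tuple[float, bool]:
        """Deterministic 1-D minimisation of the projected SS over log10 K."""
        lo, hi = LOGK_BOUNDS

        def ss(logK: float) -> float:
            return self._project(self._design(logK), Y)[1]

        grid = np.arange(lo, hi + 1e-12, _LOGK_GRID_STEP)
        ss_grid = np.array([ss(g) for g in grid])
        k = int(np.argmin(ss_grid))
        a = grid[max(k - 1, 0)]
        b = grid[min(k + 1, len(grid) - 1)]
        res = minimize_scalar(
            ss, bounds=(a, b), method="bounded", options={"xatol": 1e-12}
        )
        logK = float(res.x)
        at_bound = logK <= lo + 1e-6 or logK >= hi - 1e-6
        return logK, (bool(res.success) and not at_bound)

    def _stderr(self, logK: float, coeffs: np.ndarray, Y: np.ndarray) -> float:
        """σ(log10 K) from the Gauss–Newton covariance of (logK, Δε_c).

        Residuals r_ij = y_ij − Δε_j·x_i(K); the Jacobian is analytic:
        ∂r/∂Δε_j = −x_i and ∂r/∂logK = −Δε_j·dx_i/dlogK.  The (logK, logK)
        entry of (JᵀJ)⁻¹, scaled by SSR/(N−p), gives the variance.
        """
        x = self._design(logK)
        dx = self._design_dlogK(logK)
        n_pts, n_wl = Y.shape
        # Block structure: JtJ = [[a, b_j], [b_j, d δ_jk]] with
        # a = Σ_j Δε_j² Σ_i dx_i², b_j = Δε_j Σ_i x_i dx_i, d = Σ_i x_i².
        a = float(np.sum(coeffs**2) * (dx @ dx))
        d = float(x @ x)
        b = coeffs * float(x @ dx)
        # Schur complement for the logK block.
        denom = a - float(np.sum(b * b)) / d if d > 0 else a
        N = n_pts * n_wl
        p = 1 + n_wl
        if denom <= 0 or N <= p:
            return float("nan")
        resid = Y - np.outer(x, coeffs)
        s2 = float(np.sum(resid * resid)) / (N - p)
        return math.sqrt(s2 / denom)

    # -- public fitting API --------------------------------------------------

    def fit(self, wavelength: float | None = None) -> "BindingFitResults":
        """Fit log10 K (and the complex band) by least squares.

        With ``wavelength`` given, the classical saturation-curve fit at one
        wavelength; otherwise a global fit across the common grid, solving
        the per-wavelength complex coefficients in closed form for each
        trial K (variable projection).
        """
        if wavelength is not None:
            y = self.series.signal_at(wavelength)
            Y = y[:, None]
            wl_axis = np.array([wavelength])
        else:
            Y = self.series.signal_matrix()
            wl_axis = self.series.wavelengths
        if not np.any(Y):
            raise ValueError("no binding signal: all observations are zero")

        logK, converged = self._optimize_logK(Y)
        x = self._design(logK)
        coeffs, ssr = self._project(x, Y)
        K = 10.0 ** logK
        logK_stderr = self._stderr(logK, coeffs, Y)
        K_stderr = K * math.log(10.0) * logK_stderr

        G = self.series.guest_total
        sat = np.array(
            [speciate(G, sol.host_total, K).complex / G for sol, _ in self.series]
        )
        ill = bool(np.ptp(sat) < ILL_CONDITIONED_SATURATION_RANGE)

        resid = Y - np.outer(x, coeffs)
        rms = float(np.sqrt(np.mean(resid**2)))
        unit = self.series.points[0][1].unit
        return BindingFitResults(
            model=self,
            K=K,
            logK=logK,
            logK_stderr=logK_stderr,
            K_stderr=K_stderr,
            wavelengths=wl_axis,
            fitted_response=coeffs,
            response_unit=unit,
            residual_rms=rms,
            n_points=len(self.series),
            converged=converged,
            ill_conditioned=ill,
            saturation_fractions=sat,
            wavelength=wavelength,
        )


@dataclass
class BindingFitResults:
    """Results of a 1:1 stability-constant fit.

    ``fitted_response`` is the per-wavelength complex coefficient: with
    observations in ΔA it is Δε_complex(λ)·(1 cm basis already folded into
    the design through each point's pathlength), i.e. directly Δε_complex
    in M⁻¹cm⁻¹ when signals are differential absorbance.
    """

    model: IcdTitrationModel
    K: float
    logK: float
    logK_stderr: float
    K_stderr: float
    wavelengths: np.ndarray
    fitted_response: np.ndarray
    response_unit: Unit
    residual_rms: float
    n_points: int
    converged: bool
    ill_conditioned: bool
    saturation_fractions: np.ndarray
    wavelength: float | None = None

    @property
    def fitted_band(self) -> Spectrum:
        """The fitted complex coefficient as a Spectrum (Δε_complex scale)."""
        return Spectrum(
            self.wavelengths, self.fitted_response, Unit.DELTA_EPSILON
        )

    def predict(self) -> np.ndarray:
        """Model-predicted signal matrix at the fitted parameters."""
        x = self.model._design(self.logK)
        return np.outer(x, self.fitted_response)

    def to_dict(self) -> dict:
        return {
            "K_per_M": self.K,
            "logK": self.logK,
            "logK_stderr": self.logK_stderr,
            "K_stderr": self.K_stderr,
            "residual_rms": self.residual_rms,
            "n_points": self.n_points,
            "converged": self.converged,
            "ill_conditioned": self.ill_conditioned,
            "wavelength_nm": self.wavelength,
            "fitted_band": {
                "wavelengths_nm": self.wavelengths.tolist(),
                "values": self.fitted_response.tolist(),
            },
        }

    def summary(self) -> str:
        mode = (
            f"single wavelength ({self.wavelength:g} nm)"
            if self.wavelength is not None
            else f"global ({len(self.wavelengths)} wavelengths)"
        )
        lines = [
            "1:1 Host-Guest Binding Fit",
            "=" * 44,
            f"{'Fit mode:':<26}{mode}",
            f"{'Titration points:':<26}{self.n_points}",
            f"{'Guest total (M):':<26}{self.model.series.guest_total:.4g}",
            f"{'log10 K:':<26}{self.logK:.4f} +/- {self.logK_stderr:.4f}",
            f"{'K (M^-1):':<26}{self.K:.4g} +/- {self.K_stderr:.3g}",
            f"{'Residual RMS:':<26}{self.residual_rms:.4g}",
            f"{'Saturation range:':<26}"
            f"{self.saturation_fractions.min():.3f} - "
            f"{self.saturation_fractions.max():.3f}",
            f"{'Converged:':<26}{self.converged}",
        ]
        if self.ill_conditioned:
            lines.append(
                "Warning: saturation-fraction range < "
                f"{ILL_CONDITIONED_SATURATION_RANGE}; the curve is nearly "
                "flat and K is poorly determined."
            )
        return "\n".join(lines)

    def plot_saturation(self, ax=None):
        """Plot the observed vs fitted saturation curve (optional matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        H = self.model.series.host_totals
        if self.wavelength is not None:
            y = self.model.series.signal_at(self.wavelength)
            yhat = self.predict()[:, 0]
        else:
            j = int(np.argmax(np.abs(self.fitted_response)))
            y = self.model.series.signal_matrix()[:, j]
            yhat = self.predict()[:, j]
        ax.plot(H, y, "o", label="observed")
        ax.plot(H, yhat, "-", label=f"fit (logK={self.logK:.2f})")
        ax.set_xlabel("host total (M)")
        ax.set_ylabel(f"signal ({self.response_unit.value})")
        ax.legend()
        return ax
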