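# Methods

## Binding model

The only stoichiometry modelled is 1:1 (host + guest ⇌ complex); the
quantitative ICD analysis this package implements is specific to that case,
and drug–BCyD systems with log₁₀K ≈ 2–4 are typically well described by it.
For totals G (guest) and H (host) and association constant K (M⁻¹), the
complex concentration is the physical root of K(G−c)(H−c) = c, evaluated in
the cancellation-safe form

    c = 2GH / (S + sqrt(S² − 4GH)),   S = G + H + 1/K,

which stays accurate when binding is weak or one total dominates (the naive
quadratic formula subtracts nearly equal numbers there).  K = 0 or a zero
total gives c = 0 exactly.  Unit tests pin this root against an independent
bracketing (Brent) solver over K ∈ [1, 10⁸], G, H ∈ [10⁻⁶, 10⁻²] at 1e−10
relative tolerance.

The spectral observables are

* ICD:  ΔA(λ) = Δε_c(λ) · c · l  — the complex is the only CD-active
  species, so the band shape is fixed and only its amplitude follows the
  titration;
* UV:   A(λ) = (ε_free(λ)·(G−c) + ε_complex(λ)·c) · l — a two-state
  mixture whose apparent maximum drifts from the free-guest band toward the
  complex band as the bound fraction grows.

That contrast (drifting UV maximum, fixed CD maximum) is asserted as a
property test on generated titrations.

## Fitting

K is fitted on the log₁₀ scale.  For any trial log₁₀K the per-wavelength
complex coefficient Δε_c(λ) is linear in the model, so it is solved in
closed form (variable projection), leaving a smooth one-dimensional
residual profile in log₁₀K.  That profile is minimised deterministically: a
coarse scan (step 0.05) over log₁₀K ∈ [0, 6] brackets the minimum, then
bounded Brent polishing to xatol = 1e−12.  The single-wavelength fit is the
same machinery applied to a one-column observation matrix, so it agrees
with the global fit on a one-point grid to numerical precision — a property
the tests check.

The [0, 6] window covers the physically plausible range for cyclodextrin
complexes with generous margin (log₁₀K < 2 complexes barely produce ICD;
above ~6 the curve is saturated and uninformative).  A fit that lands on a
bound is reported as non-converged.

Standard errors come from the Gauss–Newton covariance of the full
(log₁₀K, Δε_c) parameter vector.  The Jacobian is analytic:
∂r/∂Δε_j = −x_i and ∂r/∂log₁₀K = −Δε_j · (dc_i/dK) · K ln10 · l_i with
dc/dK = (G−c)(H−c)/(1 + K(G−c+H−c)) from implicit differentiation; the
log₁₀K variance is the Schur complement of the (diagonal) Δε block, scaled
by SSR/(N−p).  σ(K) = K·ln10·σ(log₁₀K) by the delta method.

Least squares is unweighted: no instrument noise model is available for the
class of data emulated, and the generator's additive i.i.d. Gaussian noise
matches the unweighted estimator.  Fitting ellipticity versus ΔA versus Δε
changes the fitted band by a wavelength-independent factor only, so log₁₀K
is invariant to the recorded unit.

Diagnostics: when the saturation fraction c/G spans less than 0.2 across
the series, the curve is nearly flat and carries little information about
K; the fit succeeds but is flagged ill-conditioned.  Fewer than 3 points,
fewer than 2 distinct host concentrations, or an all-zero signal are
errors.

## Spectra and units

Ellipticity θ (mdeg) and differential absorbance interconvert through the
fixed spectropolarimeter convention θ[deg] = 32.982·ΔA, kept as the single
named constant `MDEG_PER_DELTA_A = 32982`.  Molar conversions use
Beer–Lambert with the *total* guest concentration and the cell pathlength;
CD units (mdeg, ΔA, Δε) and absorption units (A, ε) form two separate
conversion families and cross-family conversion is an error.  All
conversions are exact inverses of one another (round-trip property tested
to 1e−12 relative).

FFT smoothing zeroes Fourier components above a cutoff expressed as a
fraction of Nyquist (default 0.15, chosen so that a Gaussian band with 5%
additive noise is denoised — RMSE to the clean band strictly decreases —
without visibly distorting the band).  The DC term is always kept, making
the filter mean-preserving and idempotent.  Non-uniform grids are an error
unless linear resampling to the median step is explicitly requested; the
package never interpolates silently.

Band maxima are read with sub-grid precision by a quadratic fit through the
grid maximum and its two neighbours; ties break toward the lower
wavelength, and a maximum on the window edge is flagged rather than
refined.

## Cavity frame and sign rules

The cavity frame is fitted to the glycosidic (O4) bridge oxygens — the most
rigid, conformation-insensitive ring of the macrocycle — rather than to an
all-atom inertia tensor.  The origin is the O4 centroid; the axis is the
unit normal of the O4 least-squares plane (smallest principal direction of
the centred scatter), with its sign fixed by the rim convention
narrow→wide: the secondary-rim (O2/O3) centroid must sit at positive axial
coordinate (the O6 centroid, with opposite sense, is used when only the
primary rim is present; with no rim oxygens the sign is arbitrary and
flagged).  The RMS out-of-plane deviation of the O4 ring (`planarity_rms`)
reports how well the planar-ring assumption holds.  All frame quantities
are equivariant under rigid motions, verified under 100 random
rotation+translations at 1e−9.

A chromophore centroid is *inside* the cavity when its axial distance from
the O4 plane is ≤ 4.0 Å and its radial distance ≤ 1.0 × the O4 ring radius
(both boundaries closed; both thresholds configurable).  The defaults come
from canonical β-cyclodextrin dimensions (cavity depth ≈ 7.9 Å, O4 ring
radius ≈ 5 Å).

The dipole–axis angle is θ = arccos(|d̂·â|) ∈ [0°, 90°] — a transition
dipole has no physical sign.  The sign call uses the orientation factor
(3cos²θ − 1)/2: inside the cavity, θ below the magic angle (54.7356°)
predicts a positive band and above it a negative band; outside the cavity
both reverse.  Within ±5° of the magic angle (configurable) the factor is
too close to zero and the call is *indeterminate*.  The ±5° band
operationalises the qualitative parallel/perpendicular rule; the underlying
coupled-oscillator theory changes sign exactly at the magic angle.

The end-to-end predictor requires the dipole vector and the structure to
share one coordinate frame; it never guesses a frame transformation.  The
bundled reference dipole table (TDDFT components for four drug guests, free
and complexed) is given in the lab frame of the underlying excited-state
calculation, so it supports magnitude checks but not angle computations.

## Synthetic data

The generator emulates the experimental design the analysis assumes:
Gaussian bands in wavelength, a fixed guest concentration, host:guest
ratios stepped up the saturation curve, and additive i.i.d. Gaussian noise
applied last (seed mandatory; all outputs bit-reproducible per seed).

The default scenario is fenoprofen-like: 0.4 mM guest in a 1.0 cm cell,
ratios 0/5/20, a free UV band at 270.6 nm (ε ≈ 1400 M⁻¹cm⁻¹) with a ~3 nm
bathochromic and hyperchromic shift on complexation, a structured two-band
complex CD (274.6/280.6 nm, Δε ≈ 1.6/2.0 M⁻¹cm⁻¹ — vibronic structure is
emulated by allowing several narrow bands per spectrum), and
log₁₀K = 3.06.  A nimesulide-like scenario (391.4 nm band, ~10 nm shift,
ratios up to 30×) covers the large-shift regime.  Relative noise levels are
converted to absolute σ as a fraction of the noise-free peak signal of the
most saturated point.

What the generator does **not** emulate: baseline drift and correlated
instrument noise, vibronic band asymmetry, solvent and blank artefacts,
competing stoichiometries, and any quantitative imitation of the real
spectra of the four drugs.  Passing recovery tests therefore demonstrate
the estimator's correctness and noise behaviour under the stated model, not
robustness to systematic instrumental error.

Toy geometries are idealised oxygen scaffolds: n equally spaced O4 atoms
(default 7, β-cyclodextrin-like) on a 5.0 Å ring at z = 0, an O6 ring at
z = −2 Å with 0.8× radius (narrow rim) and O2/O3 rings at z = +2 Å with
1.2× radius (wide rim), with optional seeded Gaussian jitter.  They
exercise the frame fitting, rim-orientation convention and sign rules; they
are not conformational models of a real macrocycle.

## Problem sizes

Tests and the acceptance script run on 161-point wavelength grids, 3–6
titration points, and up to 100 replicate fits or rigid motions; a full
suite completes in a few seconds.  These sizes were chosen because the
estimator's behaviour is already fully exercised at them: the variable
projection is exact at any grid size and the replicate count bounds the
Monte-Carlo error of the mean-recovery checks well below the asserted
tolerances.

## Known limitations

* Only 1:1 binding; no Job-plot or higher-stoichiometry analysis.
* No automated chromophore perception — the chromophore atom set (or its
  centroid) is selected by the caller.
* No rotational-strength (Rosenfeld) calculation; the sign rules are
  geometric, and predictions within the indeterminate band around the magic
  angle are deliberately withheld.
* Vendor binary spectrometer exports are not parsed; a documented
  plain-text dialect (header + two columns) stands in for them.
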