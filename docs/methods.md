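# Methods

This note records the model conventions, numerical choices and design
decisions behind `hydrep`, and what the synthetic-data tests do and do
not demonstrate.

## Landau–Ginzburg model and conventions

All energies are β-rescaled (units of kT), lengths are nm, charges
elementary charges; pressures are kT/nm³ internally with conversion to
bar from the configured temperature (1 kT/nm³ = 41.4 bar at 300 K).
The functional is

βF/A = ∫_{−d/2}^{+d/2} dz [ (a/2) m² + (b/2) m′² ] − h₊ m(d/2) − h₋ m(−d/2),

with walls as sharp planes at z = ±d/2 and delta-function surface
coupling; a finite coupling width is deliberately not modelled.
Variational minimization gives a m = b m″ in the bulk and the natural
boundary conditions b m′(±d/2) = ±h± (outward normal per wall). Two
boundary families are implemented:

- **fixed_field** — h± prescribed. Antisymmetric data (h₊ = −h₋ = h,
  the symmetry-dictated case for a parity-odd order parameter between
  identical surfaces) give m(z) = (h/aλ) sinh(z/λ)/cosh(d/2λ),
  m_s = (h/a)/λ·tanh(d/2λ), βF/A = −(h²/aλ) tanh(d/2λ) and
  βΠ_ind = (h²/b)/(1+cosh(d/λ)), repulsive with large-d tail
  2(h²/b)e^{−d/λ}; the combination h²/b is quoted as the tail
  amplitude. Symmetric data (h₊ = h₋) give the cosh profile,
  βF/A = −(h²/aλ) coth(d/2λ) and the attractive
  βΠ = −(h²/b)/(cosh(d/λ)−1).
- **fixed_order_parameter** — the wall value m_s prescribed
  (Marčelja–Radić-style). Antisymmetric: βF/A = aλm_s² coth(d/2λ),
  repulsive βΠ = a m_s²/(cosh(d/λ)−1); symmetric: attractive.

**Sign structure.** The first integral of the Euler–Lagrange equation
evaluated at the midplane gives the exact disjoining pressure
βΠ = (b/2) m′(0)² − (a/2) m(0)², so *the profile symmetry class alone
fixes the sign for any boundary condition*: antisymmetric ⇒ repulsion,
symmetric ⇒ attraction. The often-quoted sign change when switching
between the two boundary-condition families arises because the naive
transplantation of boundary data changes the symmetry class: imposing
the same-sign surface *amplitude* through a fixed field produces the
symmetric (attractive) profile, whereas the fixed-value condition with
antisymmetric data is the classic exponential repulsion. The package's
sign-law tests implement exactly this comparison at matched surface
amplitude. Both statements are verified against the discrete minimizer.

**Parameterization.** `LGParameters` stores (a, b, h) and accepts the
fit-friendly (a, λ, h/a) triple; conversion is exact (b = aλ²) and
tested. For bulk water the stiffness follows from the longitudinal
dielectric response as a = 2π ℓ_B^vac/(1 − 1/ε) with the vacuum Bjerrum
length ℓ_B^vac = βe²/4πε₀ (55.7 nm at 300 K) and the SPC/E
permittivities ε = 71 (300 K), 62 (330 K), giving 355 and 323 nm/e².

## Discrete functional minimizer (oracle)

Uniform grid, trapezoidal quadrature for the m² term, midpoint
differences for m′², surface terms on the end nodes (or Dirichlet end
values). Stationarity is a symmetric positive-definite tridiagonal
system solved directly; the scaled residual must be ≤ 1e−10 (raised as
a convergence error otherwise). The scheme is second-order in the grid
spacing (verified by Richardson refinement) and serves as the
independent oracle for every closed form; pressures are cross-checked
through central differences of the minimized free energy
(Π = −∂(F/A)/∂d to 1e−4 relative at Δd = 1e−5 nm).

## Multipole decomposition

Per-molecule z-moments about the reference site (the water oxygen):
p_z = Σqᵢδzᵢ, q_zz = Σqᵢδzᵢ², o_zzz = Σqᵢδzᵢ³ (raw, non-traceless
moments; p_z is reference-independent for neutral molecules, the higher
moments are not). Moments are deposited in the half-open bin
[z, z+Δz) of the reference site and divided by the bin volume; z is
measured from the slab midplane. The polarization composition

m(z) = p̄_z − ½ ∂_z q̄_zz + (1/6) ∂_z² ō_zzz

follows from the bound-charge identity m(z) = −∫ ρ̄ dz′, which
`bound_charge_polarization` evaluates exactly from all partial charges
and which fixes all signs and prefactors operationally. Derivatives are
central differences; optional Gaussian smoothing (σ in bins) is
available but off by default so oracle comparisons are unbiased.

**Truncation behaviour.** The expansion parameter is (molecular extent)
/(profile feature scale). In slab interiors, where profiles vary on the
correlation length, adding the quadrupole and octupole terms shrinks
the deviation from the bound-charge oracle monotonically to ~1–2%
pointwise. In the interfacial band, where the density decays over
≈0.2 nm (twice the O–H bond), the series converges slowly and the
pointwise deviation saturates near 6% of the profile maximum; the
package therefore quotes oracle agreement as the RMS residual relative
to max|m| (≤ 5% under the documented slab conditions) and reports the
monotone max-norm improvement separately. Moments beyond the third are
out of scope.

## Separations and Gibbs surfaces

d_w = N_w·v_w/A with v_w = 0.0304 nm³; d_s is the difference of mean
headgroup z positions (oxygen for alcohol-like, phosphorus for
DPPC-like surfaces, selected by a config pattern) and d = d_s − d_s⁰
with the zero-hydration offsets 0.27 nm (decanol-like) and 0.46 nm
(DPPC-like). The Gibbs dividing surfaces use the standard equal-area
construction per interface on the laterally averaged density, with the
bulk density estimated from the central 20% of the slab; a missing
plateau triggers a warning and a flagged best-effort result. The two
definitions agree within two bins on generator output.

## Thermodynamics

Π = Π_osm + (μ − μ_osm)/v_w is implemented exactly linear (first order
in Π − Π_osm; no compressibility corrections). The constant-volume
protocol interpolates N_w(μ) and Π(μ) with monotone piecewise-cubic
(PCHIP) splines and refuses extrapolation; either monotone direction of
μ(N_w) is accepted, since a net-repulsive system has μ decreasing
toward the bulk value as water is added.

## Fitting chain

Nonlinear least squares (trust-region, bounded) with multi-start
initialization: λ₀ from the log-slope of the two largest-d points
(pressures) or a small ladder of fractions of d (profiles); amplitude
from the first point. Weights are uniform unless per-point
uncertainties are supplied; uncertainties come from the Jacobian-based
covariance (no bootstrap by default). Reported 1σ errors are only
calibrated when the supplied weights reflect the noise model — the test
suite checks 3σ coverage with known multiplicative noise.

- Profile fits use m(z) = m_s sinh(z/λ)/sinh(d/2λ); profiles whose even
  component exceeds half the odd component are rejected (model
  mismatch). On generated slabs the interfacial taper band is cropped
  before fitting, because the bulk sinh shape applies to the plateau
  region only.
- Surface-value fits hold λ fixed (taken from the profile fits) and
  solve the one-parameter linear problem for h/a in closed form.
- Indirect-pressure fits use Π = K/(1+cosh(d/λ)) with (K, λ) free after
  excluding nonpositive points (recorded in the result); with h/a
  supplied, the stiffness follows as a = Kλ²/(h/a)² with first-order
  error propagation.
- Total-pressure fits use A e^{−d/λ̃} after excluding strictly negative
  points; zeros are retained. All positive-pressure points enter the
  fits (no d-range restriction).
- The parameter table chains the stages per system and order-parameter
  kind; variant stiffnesses a^(k) reuse the single (K, λ_Πind) fit with
  the per-kind h^(k)/a^(k). Missing stages leave empty cells plus a
  message, never an exception.

## Synthetic-data generator

The generator produces the statistical structure the analysis consumes,
not a liquid: molecules do not interact, so there is no hydrogen-bond
network, no layering oscillations, no gel-phase packing, and surfaces
are implicit boundaries. Waters are rigid 3-site SPC/E templates
(O–H 0.1 nm, 109.47°, q_O = −0.8476 e; |p| = 4.893×10⁻² e·nm). Oxygen
positions fill the slab at bulk packing (area defaults to N_w·v_w/d)
with a flat interior density that decays to zero over a 0.2 nm cosine
ramp at each wall — an idealized interfacial width for rigid polar
surfaces — inside a box with 0.2 nm vacuum margins so molecules never
wrap across z. Orientations are drawn from the exponentially tilted
axial distribution p(u_z) ∝ exp(α(z)u_z) with α from inverting the
Langevin function (bracketed root finding to 1e−10 on a 256-node grid,
monotone interpolation between nodes) so the mean dipolar density
follows the sinh target; unattainable targets (|⟨u_z⟩| ≥ 1) raise an
error naming the offending z. Azimuth and spin are uniform. All
randomness flows through one seeded generator; identical specs produce
bit-identical output.

Pressure curves come from the closed-form indirect pressure plus an
attractive exponential direct part (default amplitude 200 kT/nm³, decay
λ) chosen so the total stays repulsive while the direct part is
attractive — the qualitative structure of the simulated decomposition.
Multiplicative Gaussian noise (default 5%) is applied to the direct and
indirect parts; the total is their exact sum. Chemical-potential curves
map N_w to a separation at fixed area, take the noiseless total
pressure, and invert the Gibbs–Duhem form, so the planted crossing of
the bulk chemical potential is exact by construction.

Because the generator plants exactly the profile and curve shapes the
model predicts, passing round trips demonstrate that the analysis
chain is unbiased and internally consistent at realistic noise and
sample sizes — not that the model describes any particular real
surface. Problem sizes used by the shipped protocols: 5×10⁴ molecules
for profile recovery (0.025 nm bins), 4×10⁵ for multipole-oracle
comparisons (0.05 nm bins), 19–25 separations and 20 replicates for
pressure round trips.

## Known limitations

- Scalar, laterally averaged order parameter only; no vectorial or
  laterally modulated structure, no wave-vector-dependent coefficients.
- Sharp-wall surface coupling; the interfacial taper exists only in the
  synthetic slabs, not in the continuum model.
- The multipole series is quoted through the octupole term; it is not
  reliable pointwise where profile features are finer than ~2 molecular
  lengths (hard density edges).
- Jackknife/bootstrap uncertainties and experimental-curve fitting are
  not implemented.
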