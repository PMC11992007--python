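# Methods

## Transport model and its assumptions

The package models a broad proton beam along a single ray through a
homogeneous medium. Energy loss is continuous slowing-down governed by
the Bragg–Kleeman power law `R = α·E^p`, equivalently the stopping power
`S(E) = E^(1−p)/(α·p)` (MeV/cm). This is adequate in the therapeutic
50–250 MeV window; it neglects relativistic corrections, energy-loss
straggling, multiple Coulomb scattering and nuclear interactions, so
computed entrance-region doses omit the build-up that nuclear secondaries
produce in measured curves. The fluence `u(z, E)` obeys the conservative
transport equation `∂z u + ∂E (S u) = 0` with inflow spectrum `g(E)` and
is given in closed form by integration along the characteristics
`E^p = E0^p − z/α`. Media are homogeneous: `α` and `p` are constants, and
the shipped registry (water, muscle, bone, lung, plus an alternative
water parameterisation with `α = 0.0022, p = 1.77`) stores one pair per
medium. Mass density defaults to 1 g/cm³ for all registry media — the
published table gives none, and `α` already absorbs density and
composition effects in the range fit; `ρ` only rescales dose per unit
mass.

Spectra are non-negative Gaussian mixtures truncated to an energy window
`[E_min, E_max]`. The window's lower edge defaults to 0.1 MeV: the model
needs `E_min > 0` because `S` diverges at zero energy, and a 0.1 MeV
proton has sub-micrometre residual range, irrelevant at centimetre scale.
Tabulated (non-Gaussian) spectra are out of scope. The normalisation
constant ties the *window* integral of `g` to the prescribed total
fluence (adaptive quadrature over the component's 10σ support — a plain
adaptive pass over the whole window can step entirely over a
quasi-monoenergetic peak); band integrals elsewhere use the exact erf
closed form of the same truncated mixture.

## Quadrature

All depth quantities are single energy integrals evaluated per Gaussian
term in mapped variables. With `E'` the initial energy of the particle
observed at depth `z` (`E'^p = E^p + z/α`) the fluence measure collapses
to `u dE = g(E') dE'`, which gives particle-number conservation exactly
and reduces `∫u dE` to an erf evaluation. Writing `s` for the residual
energy at depth,

* `∫ u S dE = (αp)⁻¹ ∫ g(E'(s)) E'(s)^(1−p) ds` — smooth integrand;
* `∫ u S² dE = (αp)⁻² ∫ s^(1−p) g(E'(s)) E'(s)^(1−p) ds` — integrable
  endpoint singularity `s^(1−p)` at the track end.

Each term is integrated on its own mapped 8σ support (narrow, separated
components stay resolved; truncation error ~1e−15 of the mass). The
singular factor is handled by splitting at a residual energy of 1 MeV
(micrometres of range): below the split the substitution
`s = t^(1/(2−p))` absorbs the singularity exactly; above it the integrand
is smooth in `s`. Fixed 256-node Gauss–Legendre quadrature per
region then reaches machine precision on these analytic integrands (the
test suite checks node-doubling stability at 1e−6), and the whole scheme
broadcasts over depths and over batches of `(α, p)` samples, which is
what makes 25,000-sample Monte-Carlo loops take minutes. The `S²`
integrals require `p < 2` — at `p = 2` the track-end singularity becomes
logarithmically divergent — and the code raises rather than regularises;
all registry media have `p ≤ 1.77`.

Dose is kept internally in MeV/g and converted to Gy (×1.602176634e−10)
only at output; LET converts MeV/cm → keV/μm (×0.1). Depths where the
denominator fluence (or dose) has vanished report LET (or RBE) as 0 with
a boolean mask rather than NaN, so downstream biology stays finite.
Curve peaks are located by grid argmax plus parabolic refinement through
the three neighbouring points, ties breaking toward smaller depth; a flat
curve returns 0 with a degenerate flag.

## Radiobiology

Photon survival is linear-quadratic, `SF = exp(−c_X-ray·D − β·D²)`; for
protons the linear coefficient grows linearly with dose-averaged LET,
`c = c_X-ray + λ·L_D`, with `λ` and `β` constant per cell line (two
shipped lines: AG01522 skin fibroblasts, c_X-ray = 0.54 Gy⁻¹, λ = 0.0451
μm keV⁻¹ Gy⁻¹, β = 0.051 Gy⁻²; U87 glioblastoma, 0.11, 0.0127, 0.059).
The equivalent photon dose inverts the photon LQ curve; the root is
evaluated as `2K/(c + √(c² + 4βK))`, which avoids the catastrophic
cancellation of the textbook quadratic formula as `β → 0` and passes
smoothly through the linear limit. RBE is the ratio of equivalent photon
dose to proton dose; past the range it degenerates to 0/0, so points with
dose below 1e−6 of the curve maximum (configurable) are masked, not
extrapolated. Biological (LET-weighted) dose `BD = D(1 + (λ/c_X-ray)L_D)`
is the negative log-survival of the linear-exponential model scaled by
`1/c_X-ray`. Curve-level operations refuse dose curves not tagged Gy
rather than converting silently.

## Uncertainty quantification

`α` and `p` are independent normals. Built-in standard-deviation cases:
absolute `(1e−4, 1e−4)`; relative, 1% of the means; empirical, published
95% half-widths for water `(0.00025, 0.02)` scaled by 1/1.96 (treating
the intervals as ±1.96σ), i.e. `(0.000128, 0.0102)`. Local sensitivity is
examined at three characteristic depths of a Bragg curve — A halfway to
the peak, B at the peak, C at the steepest distal gradient — via dose
contours over the ±2σ phase square and the active-subspace direction:
the dose gradient at the mean in σ-standardised coordinates (central
differences, step 0.1σ, halving-stable to 1e−3), whose normalised form is
the dominant eigenvector of its own rank-one outer product.

Global propagation draws `(α, p)` samples (tail draws with `α ≤ 0` or
`p ≤ 1` are rejected and redrawn — at the shipped σ values the rejection
rate is ≈ 0 — and the count is logged on the result), recomputes the
analytic dose curve per draw in vectorised batches, and reports
linear-interpolation empirical quantiles: per-depth 68%/95% bands for
`D(z)` and quantile intervals for the refined peak depth. The nominal
curve `D(z; μ_α, μ_p)` is reported alongside; it is *not* the ensemble
mean and need not lie inside the bands. Everything is seeded and
replay-exact.

The acceptance script reports the 95% peak-depth half-width for a 62 MeV,
5% spread beam at the empirical σ case with 25,000 samples on a 0.01 cm
grid over [0.5, 6] cm. Note what the model itself implies for this
number: the peak depth tracks the range `α·62^p`, whose relative
dispersion under the empirical σ values is
`√((σ_α/μ_α)² + (ln 62·σ_p)²) ≈ 6.7%`, so the 95% half-width is
`1.96 × 0.067 × 3.37 cm ≈ 0.44 cm` (the computed value, 0.41 cm, is
slightly below because the 5% energy spread flattens the peak). A
half-width of ~1 cm is not attainable from this distribution — even a
simultaneous +2σ deviation of both parameters shifts the peak by only
~0.65 cm; ~1 cm corresponds instead to the extreme-sample envelope at
n = 25,000 (≈ 4σ) or to using the unscaled half-widths as σ values.

## Planning

An SOBP plan superposes `N_y` Gaussian basis beams whose principal
energies are chosen so their ranges are equally spaced across a target
interval (inverting the range law), all sharing one variance σ² (default
examples: 30 beams, σ² = 1 MeV², ranges on [z_prox, z_dist + ¼] — the
¼ cm distal extension suppresses the edge oscillation that strictly
confined ranges produce). Dose is linear in the weights through
precomputed unit-weight influence profiles `D_i(z)`, and the LET-weighted
dose stays linear through the companion `S²` profiles `Q_i(z)`:
`D·L_D = Σ y_i Q_i`. The discrete cost keeps the printed left-difference
form `Σ_{j≥1} ½ w_j (D(y,z_j) − T_j)² (z_j − z_{j−1})` (not a symmetric
trapezoid), on a default grid of 1200 uniform points over
[0, z_dist + 2] cm. The weighting `w(z)` is piecewise constant over
tumour / organ-at-risk / healthy regions. In the survival-fraction cost
the weighting enters the same way — as a multiplier of the squared
deviation — treating the alternative placement (inside the square) as a
notational inconsistency of the source material.

Two solvers minimise the convex quadratic objectives over `y ≥ 0`
(optionally `y ≤ ub`): a bound-constrained quasi-Newton path (L-BFGS-B
from `y = 0` with analytic gradient, followed by an exact least-squares
polish on the identified active face, with convergence declared from the
KKT conditions) and a direct NNLS solve of the row-scaled design matrix,
kept as an independent oracle; their costs agree to ~1e−13 relative on
the shipped examples. Columns are scaled to unit peak response before
solving. The survival-fraction objective is genuinely nonlinear and
potentially multi-modal; it is minimised by L-BFGS-B with numerical
gradients and documented pathology: once survival is ≈ 0, additional dose
is essentially unpenalised. Survival planning needs an absolute dose
scale, supplied as `dose_scale` taking influence MeV/g to Gy (the
quadratic examples use unit-free relative dose, where the weight scale is
arbitrary).

## What the shipped configurations do and do not show

All worked configurations are built from printed constants (62 MeV beams,
the three planning examples, the parameter registries); there is no
external data. Passing tests therefore demonstrate internal consistency
of the analytic model, its quadratures, inversions and optimisers — not
agreement with measured depth-dose data, which would require the
straggling and nuclear effects this model deliberately omits. Dose
figures for the planning examples are in relative units; no published
absolute dose pins the Gy conversion, which is checked only against the
physical constant.

## Known limitations

One spatial dimension; homogeneous media only (no piecewise tissue
stacks); Gaussian-mixture spectra only; unrestricted LET (equal to
stopping power) — restricted LET with a finite cutoff is out of scope;
no fractionation, tumour-growth dynamics or TCP/NTCP endpoints; no
DICOM-RT interoperability. The `(α, p)` prior has no correlation
structure, and spectrum parameters (`E0`, ε) are treated as exact.
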