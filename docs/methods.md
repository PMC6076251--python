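# Methods

## Model

A fluctuating filament is described by overdamped Timoshenko beam
kinematics: the cross section rotates by a bending angle φ plus a shear
angle γ, with total slope ∂u/∂x = φ + γ. Four dissipation channels act:
hydrodynamic drag on the transverse velocity (per-length coefficient η,
Stokes regime, scalar — no 3-D hydrodynamic interaction tensors), and
internal friction proportional to the bending rate (η′_b), the shear
rate (η′_s), and nothing else. Inertia is neglected throughout
(overdamped limit), so there are no propagating-wave dynamics.

After a spatial Fourier transform at wavenumber q, the state
z = (φ, u) obeys C ż + K z = f with

    C = [[η′_b I q² + η′_s A,  q η′_s A],
         [q η′_s A,            η′_s A q² + η]]
    K = [[B q² + κS,  q κS],
         [q κS,       κS q²]]

in a sign convention that makes both matrices symmetric positive
semidefinite (any self-consistent convention yields the same rates; the
tests check this via the eigenvalues of the pencil). Here A = πr²,
I = πr⁴/4, B = EI, S = GA, and κ = 0.75 is the shear correction factor
of a circular section.

The two decay rates are the roots of det C · λ² − N̄ λ + det K = 0 with

    det C = η′_b η′_s I A q⁴ + η (η′_b I q² + η′_s A)
    N̄     = (η′_b I κS + η′_s A B) q⁴ + η B q² + η κS
    det K = B κS q⁴.

Squaring gives the equivalent quadratic M x² − N x + P = 0 in
x = 1/τ², with M = (det C)², N = N̄² − 2 det C det K, P = (det K)². The
reported spectra satisfy every analytic limit: the bending-only
(worm-like chain) time τ = (η + η′_b I q⁴)/(B q⁴) under a stiff-shear
limit, the drag-only time τ_d = (κSη + Bηq²)/(κSBq⁴) when η′ = 0, the
large-q plateaus (η′_b/E, η′_s/(κG)), and the small-q pair
(η′_s/(κG), η/(Bq⁴)).

### Numerical route (essential)

For table-like parameters, expanding det C, N̄ and det K from the matrix
entries cancels four or more significant digits, and the quadratic
formula's "minus" branch destroys the slow rate entirely. The
implementation therefore always evaluates the three invariants through
the closed forms above — every monomial nonnegative, no cancellation —
and extracts λ_fast from the stable branch and λ_slow from Vieta's
product λ_slow = det K / (det C · λ_fast). When det C = 0 (drag only)
the quadratic degenerates to the single finite rate det K/N̄. The test
suite certifies this route against generalized eigenvalues of (K, C)
computed in exact rational arithmetic at 70 decimal digits, because
double-precision QZ itself cannot resolve rate ratios beyond ~10
decades.

### Autocorrelation amplitudes

White thermal forcing with two-sided spectral density `noise_level`
enters the displacement equation only. The displacement power spectrum

    S_u(ω) = noise_level (k₁₁² + ω² c₁₁²) / [det C² (ω²+λ₁²)(ω²+λ₂²)]

resolves by partial fractions into two Lorentzians, giving amplitudes

    R_i = noise_level (k₁₁² − λ_i² c₁₁²) / (2 det C² λ_i (λ_j² − λ_i²)).

No thermal-energy (k_BT) calibration is attempted: `noise_level`
defaults to 1 and amplitudes are relative, matching the practice of
fitting R₁, R₂ as free parameters. An amplitude can in principle be
negative (the residue formula does not impose positivity); positivity
is checked downstream rather than enforced. Whether thermal forcing
should also enter the rotation equation for strict
fluctuation–dissipation consistency is left open by the governing
formulation as used here; the simulator exposes `rotational_forcing`
for exploring that variant, documented as an extension. Forcing
placement changes amplitudes only, never the relaxation times.

A consequence worth knowing: with displacement-only forcing at the
chromosome arm's dominant wavenumber, the slow (shear-like) component
carries under 1% of the zero-lag variance. Experimental
autocorrelations show a much stronger slow component; the synthetic
fitting tests therefore either scale measurement noise to the smallest
amplitude being recovered or use comparable amplitudes directly, and
passing them demonstrates estimator correctness, not that
variance-scale noise on this particular amplitude ratio would be
surmountable (it is not, for any estimator — verified by fits started
at the truth).

## Fitting

Mono- and bi-exponential models are fitted by bounded trust-region
least squares. The bi-exponential fit uses ≥ 10 starts with time pairs
log-spaced across the lag span plus a start derived from the mono fit;
two-exponential fitting is ill-conditioned when the two times are
within a factor of ~3, and multi-start is the standard defence. Results
are normalised to τ₁ ≤ τ₂, and the mono model is nested, so the
bi-exponential residual sum of squares never exceeds the mono one (a
fallback enforces this in pathological cases and flags
non-convergence). Fits are unweighted by default (whether experimental
fits weighted the growing lag-variance is unknowable from the published
record); `ACFSeries` accepts optional weights. The fit-quality measure
is rmse = sqrt(∫(data − model)² dT / (T_max − T_min)), with the raw
square-root-of-integral variant also exposed; published rmse values
depend on the experimental curves and are not reproduced.

## Coefficient inversion

Three routes, in increasing sophistication:

- **large-q limit**: η′_b = τ₁E, η′_s = τ₂κG — exact on the plateaus;
- **bending-only**: η′_b = τE − η/(Iq⁴), flagged unphysical if drag
  exceeds the fitted time's dissipation;
- **full**: at fixed spectrum, the rate-sum and rate-product relations
  give one linear and one bilinear equation in (η′_b, η′_s), reducing
  to a quadratic in η′_b — so the inversion generically has **two**
  solutions, corresponding to assigning the bending-like branch to the
  fast or the slow time. `invert_full` returns the candidate nearest
  (in log space) the large-q seed, polished by Newton steps on the
  stable forward map and verified to relative residual < 1e-9;
  `invert_full_candidates` exposes both.

The dominant wavenumber of a cantilevered arm uses the unrounded
q = π/(2L); feeding the rounded printed wavenumbers shifts times by
~7% and breaks table self-consistency. Disambiguation between the two
orderings a fit produces scores each assignment by the worse
coefficientwise relative gap between the full-model and limit
estimates, requiring positivity.

Identifiability: when drag dominates the damping determinant, the two
times barely depend on the internal coefficients and no inversion can
recover them (the closed form still reproduces the requested spectrum
exactly — the roundtrip tests restrict to the internal-friction-
dominated regime for this reason). No uncertainty propagation from the
fit covariance is attempted.

## Length scaling

`tau_drag_of_length` is algebraically identical to the drag-only
dispersion at q = q*/L. The default q* = π/2 is the fundamental
cantilever mode, matching the dominant-wavenumber convention; it is
configurable because experimental length-scaling data do not pin it.
The fit of τ = aL⁴ + bL² is linear in the (L⁴, L²) basis; log-space
minimisation (default) suits the multiplicative scatter evident on
log-log experimental axes and keeps both coefficients nonnegative.
Input relaxation times are treated as autocorrelation-decay times; a
mean-squared-displacement definition differs only by a factor
convention and does not affect the exponents or the crossover.

## Mode criterion

Cantilever mode wavelengths use λ_n = 2L/((2n−1)π), the reciprocal of
the clamped-free wavenumber q_n = (2n−1)π/2L (no full eigenfunction
computation — the sinusoidal approximation is the one the criterion is
stated in). Shear dominates when λ_n/r < threshold (default 10). With
the standard microtubule outer radius of 12.5 nm this reproduces the
published mode table for L = 2 μm (shear from n = 6) and L = 10 μm
(from n = 26); for L = 30 μm the closed form gives shear dominance from
n = 77 while the published rounding prints the boundary as "n > 77" —
an off-by-one internal to that tabulation, reported here from the
closed form.

## Simulator and synthetic data

Euler–Maruyama on C ż = −K z + f with per-step displacement forces of
variance `noise_level/dt` — the discretisation under which the
stationary statistics converge to the analytic autocorrelation model
above (an alternative convention with twice that variance would double
every amplitude while leaving the times untouched). The time step must
stay below a tenth of the fast relaxation time; the induced first-order
bias on recovered times is ~dt·λ_fast/2 and is covered by a
dt-refinement test. Because the recursion is linear with constant
coefficients, it is evaluated exactly through a diagonalised recursive
filter (two scalar AR(1) filters in the eigenbasis of the step matrix),
making 10⁷-step runs take seconds; a plain loop handles the
non-diagonalisable corner. Drag-only filaments have singular C; the
rotation is then slaved to the displacement and a scalar
Ornstein–Uhlenbeck recursion is integrated instead. All generators are
bit-reproducible given a seed.

The synthetic factories emulate the two experiment types: (a) noisy
bi-exponential autocorrelations (model curve plus i.i.d. Gaussian
noise on a lag grid) and (b) relaxation-time-versus-length tables with
unit-mean lognormal noise of chosen coefficient of variation over
lengths 2–30 μm. The microtubule-like defaults (E = 1.2 GPa,
G = 1.5 kPa, r = 12.5 nm, η = 2×10⁻³ kg/(m·s)) take the bending
modulus, the strongly anisotropic (kPa-scale) shear modulus and
slender-body drag in water from standard literature ranges; together
they put the L⁴/L² crossover near 10 μm, where the microtubule
experiments place it. What the synthetic data do **not** contain:
correlated autocorrelation-estimator noise (except in full simulator
runs), drift, tracking error, or length-dependent drag corrections —
so passing recovery tests shows estimator correctness under the stated
noise model, not robustness to every artefact of real trajectories.
Spatial fields are not simulated; the analysis is modewise, and
`superpose_modes` offers only a visualisation-grade sum of sinusoidal
cantilever shapes.

## Test problem sizes

Ensemble fitting tests use 2000-point lag grids over eight slow times
(the density of autocorrelations computed from minutes of video-rate
tracking); Langevin recovery tests average the autocovariance of ten
independent 4×10⁶-step runs (4×10⁵ slow times of signal in total),
chosen so estimator noise sits below the smallest amplitude being
recovered. The plateau-threshold checks at 0.06 and 0.007 μm⁻¹ are run
at the stiff end of the internal-viscosity ranges they were surveyed
over (10⁴ and 10⁶ kg/(m·s)); with the fitted chromosome coefficients
the 5% plateau-entry wavenumbers are larger (~0.13 and ~0.04 μm⁻¹),
though still below the shortest arm's dominant wavenumber of
0.22 μm⁻¹, which is what the coefficient-from-limit readings rely on.

## Known limitations

- Branch identity (bending-like vs shear-like) is reported by
  comparison with the limits, not encoded in the τ₁ ≤ τ₂ ordering,
  which swaps physical branches across the spectrum crossing.
- The full inversion's two-solution structure means a bi-exponential
  fit alone cannot fix the coefficients; external information (the
  limit consistency used here, or prior knowledge of either
  coefficient) is required.
- No rotational drag on φ, no mode-mode hydrodynamic coupling, no
  absolute amplitude calibration.
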