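# Methods

## Model

The package studies the activator-depleted (Schnakenberg) reaction–diffusion
system on the unit reference domain Ω₀ = [0,1]^m (m = 1, 2),

    u_t + m (ρ̇/ρ) u = (1/ρ²) Δu + γ (a − u + u²v)
    v_t + m (ρ̇/ρ) v = (d/ρ²) Δv + γ (b − u²v)

with homogeneous Neumann boundary conditions. Uniform isotropic domain
growth x(t) = ρ(t)·x(0) is pulled back to the fixed reference domain, which
adds the dilution term m·ρ̇/ρ and rescales diffusion by ρ⁻². The spatially
homogeneous steady state is (u*, v*) = (a+b, b/(a+b)²); diffusion-driven
(Turing) instability of that state requires the four strict inequalities on
(f_u, f_v, g_u, g_v) evaluated there — negative reaction trace, positive
determinant, positive d-weighted trace, positive discriminant. Membership,
uniform sampling (rejection) and area estimation (midpoint grid
classification) of this Turing space are provided; boundary points count as
outside because the conditions are strict.

One quantitative caveat discovered while validating the geometry: inside
the vague prior box [0.1, 10]², at d = 10, the Turing space has area
≈ 0.0123 (grid estimates at resolutions 800–3200 agree to ~1%, and an
independent dispersion-relation eigenvalue scan confirms the inequality
implementation). The box is therefore ≈ 8×10³ times larger than the Turing
space — three orders of magnitude, not the "order 100" sometimes quoted for
this system; the square root of the ratio (≈ 88) does match a comparison of
linear scales. The package reports the honest area ratio.

## Inverse problem

The data are the noisy final-time fields y = G(p) + η, both components at
every grid node, with η zero-mean Gaussian, independent across nodes, and
per-component standard deviation equal to a fixed fraction (5% or 10%) of
that component's noiseless spatial range — u and v get their own σ because
their ranges differ. The misfit potential is

    Φ(p; y) = Σ_c Σ_i (G(p)_{c,i} − y_{c,i})² / σ_c²

with no ½ factor. This convention is fixed project-wide; it sets the
posterior temperature, and the conjugate-Gaussian test oracles account for
it (a Gaussian likelihood exp(−Φ) has covariance σ²/2 per coordinate).
σ is treated as known by the sampler, as in synthetic studies. Forward-model
failures (scheme blow-up, non-positive growth curve, failed steady-state
seeking, invalid parameters) map to Φ = +∞, i.e. certain rejection, rather
than aborting a run. Φ uses the unweighted sum over nodes; on a fixed grid
a grid-weighted norm differs only by a constant factor absorbable into σ.

## Forward solver

Space: vertex-centered finite differences on [0,1]^m with the standard
3-point/5-point Laplacian stencil; Neumann conditions via mirrored ghost
nodes. Time: first-order semi-implicit backward Euler (IMEX) with a single
lagged Picard iterate for the nonlinear reactions — diffusion, dilution and
the linearized reactions are implicit, and (ρ, ρ̇) are frozen at t_n within
each step. The v-equation diffuses v (with coefficient d); a printed source
of this scheme carries Δ_h u in the second equation, which we read as a typo
since the continuous system diffuses v.

Linear systems: in 1-D a direct tridiagonal factorization (LAPACK gtsv); in
2-D the system is symmetrized with trapezoidal node weights (½ on faces, ¼
at corners — making the weighted Laplacian symmetric negative
semi-definite) and solved by a direct banded factorization (LAPACK gbsv,
bandwidth = nodes per axis). Direct solves were chosen after observing that
at coarse time steps the u-equation's shifted diagonal 1/τ + γ(1 − uⁿvⁿ)
passes through zero as the pattern amplitude grows, leaving an indefinite
or near-singular system on which CG and MINRES stagnate; banded LU agrees
with dense reference solves to machine precision and costs ≈ 90 µs per step
on a 13×13 grid.

Empirical stability: the lagged-Picard linearization requires γτ ≲ 0.1.
At γ = 1000, τ = 2.5×10⁻⁴ already diverges while τ = 10⁻⁴ (the reference
production value, γτ = 0.1) integrates cleanly — the scaled-down studies
below keep γτ = 0.1. Resolution must also cover the pattern wavelength
2π/k with k² ∈ γ·[0.19, 0.45] for the reference kinetics: at γ = 1000 the
wavelength is ≈ 0.3 (marginal at 33 nodes per axis), which motivates
reducing γ rather than coarsening h when scaling runs down.

Two run modes exist: fixed horizon (the last step is truncated so the
trajectory lands exactly on T) and steady-state seeking on a stationary
domain, which stops at the first step where the grid-weighted L₂ norm of
the discrete time derivative, √(h^m Σ ((wⁿ⁺¹−wⁿ)/τ)²) summed over both
components, drops below the threshold (reference value 10⁻⁵), then
continues to 2T and verifies that state(2T) differs from state(T) by less
than the threshold in the same norm. The norm's h^m weight and the
combination of both components in one Euclidean norm are our choices; the
verification leg can be skipped inside sampling loops (`verify=False`)
where the stopping rule alone suffices and every forward solve is paid for
thousands of times.

Initial conditions are the fixed, known perturbations of the homogeneous
steady state used by the reference studies: in 1-D, 0.005·Σ_{k=1..9}
sin(kπx) added to (1, 0.9); in 2-D, 0.0016·cos(2π(x+y)) + 0.01·Σ_{j=1..8}
cos(2πjx) added to the steady state of (a, b). Note the 1-D sine sum has a
nonzero mean (odd-k terms integrate to 2/kπ, total ≈ 0.0057). The 2-D
perturbation deliberately seeds 2π-periodic modes; which of them are
linearly unstable depends on γ.

## Growth families

ρ(0) = 1 exactly for all families, with analytic derivatives: constant;
exponential ρ = e^{rt} (reference rate 0.001); logistic
ρ = e^{rt}/(1 + (e^{rt}−1)/K) (reference rate 0.01). The logistic carrying
capacity defaults to K = e^{0.6} so that both reference profiles reach the
same final size at T = 600 (to 0.2%); the alternative constant e^{0.006}
printed in one source makes the final sizes differ by ×1.8, contradicting
the stated equal-final-size property, so we treat it as a typo but accept
any K explicitly.

The unknown growth function is approximated by a degree-4 polynomial in
scaled time s = t/T with three free coefficients: ρ(sT) = 1 + c₁s + c₂s² +
c₃s³ + c₄s⁴, where c₄ = ρ_T − 1 − c₁ − c₂ − c₃ absorbs the known final size
(the order-0 and order-4 coefficients are fixed by the endpoint
conditions). Scaled time keeps the basis well conditioned. Positivity of a
candidate curve is checked on a 200-point grid before any PDE solve; a
least-squares projection onto the family reproduces the exponential
reference curve to sup-error < 0.01, so the prior support covers the truth.

## Priors

* uniform box (vague knowledge: order of magnitude only),
* uniform on the Turing space within a box (instability-informed),
* independent log-normals for (d, γ): "median (5, 500), log-sd 0.95". The
  log-normal is parameterized by its median (scale) because a log-sd near 1
  spreads each component over about one order of magnitude, matching the
  stated prior spread; whether the original "mean (5, 500)" meant the
  arithmetic mean is ambiguous, and the median reading is our documented
  choice. Positivity of d is required for well-posedness.
* Gaussian on the three growth coefficients, calibrated so that 95% of
  sampled curves lie inside a prescribed pointwise envelope: the common
  multiplier of the base standard deviations is bisected until the in-band
  fraction at 10⁴ Monte Carlo curves lies in [0.94, 0.96].

The default calibration envelope is the band of constant half-width
ρ_T − 1 around the prior-mean curve 1 + (ρ_T−1)s⁴. A band of ±0.4(ρ_T−1)
around the *linear* interpolant — a plausible first guess — contains
neither the prior-mean curve (distance 0.44(ρ_T−1) at midtime) nor the
saturating logistic truth (distance ≈ 0.6(ρ_T−1)), which makes calibration
infeasible and would exclude one truth a priori; the wider quartic-centered
band contains both reference profiles.

The joint four-parameter prior is the product of the box prior on (a, b)
and the log-normal on (d, γ).

## Samplers

Acceptance: a(x, x′) = min{1, exp(Φ(x) − Φ(x′))}. An infinite proposed
potential is never accepted; an infinite current potential with a finite
proposal always moves.

Kernels: the independence sampler (fresh prior draws) and the
preconditioned Crank–Nicolson kernel m + √(1−β²)(x−m) + βξ, ξ ~ N(0, Γ).
The mean factor √(1−β²) is the prior-preserving form — it is the one that
makes the acceptance rule above correct for a Gaussian prior N(m, Γ) — and
β = 1 recovers the independence sampler; the alternative printed factor
√(1−β) is selectable (`mean_scaling="printed"`) for comparison but does not
preserve the prior away from the endpoints.

Parallel Metropolis–Hastings: each step draws N proposals from the kernel
at the current state x⁰, evaluates their potentials (optionally across
worker processes), forms the (N+1)-state transition matrix
A(i,j) = a(xⁱ, xʲ)/N off-diagonal, and resamples N states from its
stationary distribution. For this acceptance rule the stationary
distribution is softmax(−Φ) in closed form, because πᵢA(i,j) =
min(e^{−Φᵢ}, e^{−Φⱼ})/N is symmetric (detailed balance); the closed form is
evaluated with log-sum-exp shifting, and a generic left-eigenvector solver
is kept as a test oracle. When every potential is infinite the mass
concentrates on the current state (the chain holds). The next step's
reference state is the last of the N resampled states — the resampled
states are exchangeable draws from the same distribution, so any fixed
choice is valid; this one is isolated in a single place. Φ(x⁰) is cached
across steps. All proposal randomness is consumed on the coordinating
generator before evaluation begins, so chains are bit-identical for any
worker count. Proposals outside the prior support are screened to Φ = +∞
before paying for a forward solve. Default N = 8, matching one
algorithm-level parallelization width.

## Staged posterior studies

The potential landscape over kinetic parameters is glassy: each pattern
mode arrangement has its own basin, separated by ridges, with the global
basin around the truth spanning only ~10⁻³–10⁻² in (a, b) while the vague
prior box spans ~10². An independence sampler alone would need ~10⁶ draws
to localize the posterior (which is what the original full-scale
computations used); at desk scale the studies instead run a four-stage
pipeline, all randomness derived from one `SeedSequence`:

1. **Initialization** — evaluate Φ at a few candidate points: uniform
   Turing-space samples when (a, b) are inferred (patterned data cannot
   arise outside the Turing space, so this restriction is scientifically
   justified prior knowledge, and the sliver is small enough that ~16
   samples land within ~0.05 of any point in it), prior draws otherwise.
2. **Annealed descent** — short pCN chains at geometrically decreasing
   proposal scales from the best starts, keeping the best state seen.
   Run from the two best candidates because individual descents can strand
   in neighbouring mode basins.
3. **Curvature probing** — centered second differences of Φ at the located
   mode give per-coordinate Laplace scales δ/√(ΔΦ); the probe δ doubles
   until the second difference is measurable, so flat directions get wide
   proposals instead of degenerate ones.
4. **Sampling** — a parallel-MH pCN chain centred at the mode with proposal
   covariance (5·scale)² and β = 0.35 (effective step ≈ 1.75 posterior
   standard deviations). The pCN reference Gaussian is ~5× wider than the
   posterior bulk, so the bias it introduces relative to the flat/box prior
   is at the percent level in the posterior variance — negligible against
   the Monte Carlo error of the recorded sample sizes. Burn-in is then
   removed by the mean-convergence rule below.

### Scaled study conditions

These are the package's benchmark problem sizes, chosen so a study runs in
minutes on one core while preserving the scientific content (pattern
formation, identifiability, anisotropy of the credible region):

* **2-D kinetics recovery** — γ = 200 (instead of 1000), h = 1/12,
  τ = 5×10⁻⁴ (γτ = 0.1), 5% noise, steady-state threshold 10⁻⁵. Reducing γ
  lengthens the pattern wavelength to ≈ 0.7–1.0 so a 13×13 grid resolves it,
  and enlarges the stable time step proportionally; the 2π-periodic initial
  perturbation seeds unstable modes at this γ (j = 1 and the diagonal
  (1,1) mode). Candidate evaluation integrates to the fixed horizon
  T_steady recorded when the data were generated (identical to re-seeking
  the steady state for converged candidates, at half the cost). Sampling:
  40 steps × N = 8 → 320 recorded samples before burn-in removal.
* **1-D growth identification** — γ = 1000 (the reference value), h = 1/64,
  τ = 10⁻⁴, horizon T = 2 with growth rates rescaled (exponential
  r = 0.6/T, logistic r = 6/T, K = e^{0.6}) so both profiles reach
  ρ(T) = e^{0.6} as in the reference setup; 5% noise; 22 sampling steps ×
  N = 8. γ cannot be reduced here: with only one unstable mode in the band
  (γ ≲ 250), the mode exits the instability band as the domain grows and
  the pattern dies mid-run instead of tracking the domain adiabatically;
  at γ = 1000 the band holds ~3 modes and the pattern persists through T.

At these sizes the recorded sample counts (10²–10³ after burn-in) are two
to four orders of magnitude below the full-scale runs; credible regions are
correspondingly rougher, and the recovery test asserts containment of the
truth, the b/a anisotropy ratio in [2, 6] (full-scale value ≈ 3.5), and
concentration of the region to < 10⁻⁴ of the prior box, rather than the
full-scale region bounds.

## Posterior summaries

* **Burn-in**: the smallest cut B on a 5% grid of the chain length such
  that, per coordinate, the mean over samples[B:] and the mean over the
  second half of samples[B:] agree within 0.1 of the post-cut standard
  deviation; fallback 50%. This is a concrete stand-in for "checking the
  convergence of the mean"; on short i.i.d. chains the criterion is noisy
  (the two means differ by ~0.1 sd by chance at n ≈ 300), which is
  harmless — it only discards extra samples.
* **Merging**: post-burn-in samples of chains over the same parameter space
  are concatenated with a provenance column.
* **HPD regions**: Gaussian KDE (Scott's rule bandwidth) on a rectangular
  lattice (default 200 per axis) extended three bandwidths beyond the
  sample range; the region is the smallest superlevel set holding ≥ the
  requested mass. For independent Gaussians this reproduces the χ²
  ellipse geometry (2-D 95% region radius 2.448σ) rather than the product
  of marginal intervals — the correct behaviour for highest-density
  regions. Above two dimensions only pairwise coordinate projections are
  reported.
* **Growth bands**: pointwise quantile bands (not simultaneous bands) of
  the decoded curves on a uniform time grid, plus the curve at the
  posterior-mean coefficients. Band separation means the vertical intervals
  are disjoint over a contiguous sub-interval of at least 5% of the
  horizon — a conservative reading of "completely separated".

## Limitations

* The synthetic generator reproduces the model's own discretization
  (an "inverse crime" shared with the original synthetic studies): data and
  candidate solves use the same grid, so discretization error does not
  enter the residual. Real data would add model error the noise term must
  absorb.
* Initial conditions are treated as fixed and known; identifying them is
  out of scope.
* The staged pipeline is a mode-finding initialization plus a local
  sampler; it characterizes the basin containing the best located mode. At
  full scale, many independent long chains make this localization
  unnecessary; at desk scale a pathological seed could strand the descent
  in a neighbouring basin, which shows up as an inflated mode potential
  relative to the number of observations.
* Only Schnakenberg kinetics are implemented; the operation signatures
  admit other kinetics but no others are provided.
* Gradient-based kernels are deliberately absent: the observation operator
  is a PDE solve and ∇Φ is not available.
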