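# Methods

`fretkin` quantifies exchange between conformational states of single
biomolecules diffusing through a confocal detection volume, from the
photon record of a two-color (donor/acceptor) FRET experiment. This note
documents the models, the estimator choices, the synthetic-data
generator, and the numerical decisions, in that order.

## Kinetic model

Conformational exchange is a continuous-time Markov chain over `n`
fluorescence species with transition rate matrix **K** (convention
`K[i,j] = k_ij` = rate of the transition `j -> i`, ms⁻¹; columns sum to
zero). For an irreducible network the stationary vector `x_d` solves
`K x_d = 0` and the spectrum contains one zero eigenvalue plus `n−1`
negative eigenvalues `λ^(l)` whose negative inverses are the relaxation
times `t_R^(l)` seen by correlation spectroscopy.

Not every molecule exchanges: a fraction `p_d` is dynamic, the rest is
frozen in states with fractions `x_s` ("pseudo-static" on the ≲100 ms
experimental timescale). Total species fractions are
`x = p_d x_d + (1−p_d) x_s`. This static/dynamic degeneracy — species
with identical fluorescence but different mobility in state space — is
the central analysis difficulty the package addresses.

Diagonalization of the non-symmetric **K** uses the similarity transform
`S⁻¹KS` with `S = diag(√x_d)` whenever detailed balance holds (the
transform is then symmetric, giving a real spectrum and clean spectral
projectors); a general eigensolver is the fallback, with complex pairs
beyond `1e−8·max|K|` rejected. The stationary eigenvalue is identified
at tolerance `1e−10·max|K|`.

## FRET-lines and burst indicators

Per single-molecule event (burst) the analysis uses two indicators: the
intensity-based efficiency `E = N_R/(N_G+N_R)` and the
intensity-weighted mean donor lifetime `⟨τ_DA⟩_F` (estimated as the mean
donor micro time). A molecule of fixed efficiency falls on the static
line `E = 1 − ⟨τ_DA⟩_F/τ_D0`; a molecule mixing two species traces the
dynamic line, whose lifetime coordinate is the ratio of the second to
the first moment of the lifetime distribution. Only the ideal
(linker-free) static line is implemented; linker-broadened and polymer
lines are out of scope.

The dynamic shift
`ds(x) = ½(E₂−E₁)² x(1−x) / [x(1−E₁) + (1−x)(1−E₂)]`
peaks at `x_max = √(1−E₂)/(√(1−E₁)+√(1−E₂))` with
`ds_max = ½(√(1−E₁)−√(1−E₂))²`. Geometrically `ds` equals half the
vertical offset from the static line in normalized coordinates, i.e. the
per-axis component of the perpendicular displacement (the Euclidean
perpendicular distance is `ds·√2`); this reading is the unique one
consistent with the closed forms for `ds_max` and `x_max`, and the test
suite enforces that consistency.

The moment representation is defined here as
`(m₁, m₂) = (1−E, (1−E)(1−E_τ))` with `E_τ = 1 − ⟨τ_DA⟩_F/τ_D0`. Both
coordinates are affine in the occupancy, so binary dynamic lines plot as
straight segments. The within-burst efficiency variance follows from the
indicators alone: `Var(E) = (1−E)(E−E_τ)`, which also yields molecule-wise
estimates of the kinetic correlation amplitudes
(`G_GG(0) = Var/(1−E)²`, `G_RR(0) = Var/E²`, `G_GR(0) = −Var/((1−E)E)`).

## Two-state occupancy theory

Over a window of length `T`, the fraction of time `x` a two-state
molecule spends in state 1 has two point masses (no-transition events,
weights `x_eq(1) e^{−k21 T}` and `x_eq(2) e^{−k12 T}`) plus a continuous
density `ξ₁₂(x)` built from modified Bessel functions `I₀, I₁` with
prefactor `T k12 k21/(k12+k21)`. The prefactor is pinned by exact
normalization, which holds numerically to better than `1e−6` over
`kT ∈ [0.01, 10⁴]`; a guarded renormalization path exists but corrects
only sub-0.5 % quadrature residue and never triggers in practice.
Bessel factors are evaluated exponentially scaled
(`e^{−a}I_n(b) = e^{b−a}·(e^{−b}I_n(b))`, with `b ≤ a` by AM–GM), so the
density is stable to at least `kT = 10⁴`. The grid is 2001 midpoint
cells on (0,1), keeping the integrable `1/√(x(1−x))` endpoint
singularities off the nodes.

The mode `x_m` of the continuous part maps approximately linearly to the
equilibrium fraction, `x̂_d = x_lim + (1−2x_lim) x_m`, with intercept
`x_lim(kT) = (3/2)[1 + (kT/2)(1 + I₀(kT/2)/I₁(kT/2))]⁻¹` depending only
on the mean number of transitions `kT`. The analytic map is the default;
mode extraction from burst data uses a histogram with parabolic argmax
refinement, and `T` is set to the mean burst duration (configurable) as
the standard approximation for freely diffusing molecules.

## Color-FCS model

Diffusion and kinetics are statistically independent, so
`G_ab(t_c) = (1/N)·G_diff(t_c)·G_k,ab(t_c) + 1` with the 3D-Gaussian
diffusion factor `G_diff = (1+t_c/t_diff)⁻¹(1+s² t_c/t_diff)^{−1/2}`
(aspect `s = w₀/z₀ = 0.25 default`). The kinetic factor is
`G_k,ab = S_aᵀ[p_d e^{K t_c} X_d + (1−p_d) X_s] S_b /(S̄_a S̄_b)` with
per-species signal vectors `q_G = Q₀(1−E)`, `q_R = Q₀(γE + α(1−E))`
(defaults γ=1, α=0, no background; the general path is implemented).
The propagator is expanded over spectral projectors, giving a constant
plateau `1+A⁰` (the static residual, derived from the `t_c→∞` limit of
the correlation matrix rather than from the typeset amplitude sum) plus
`n−1` exponentials; amplitudes below `1e−14` are pruned. The dual-route
identity (matrix exponential vs two-state closed form) and the
cross-amplitude relation `∂_GR = −√(∂_GG ∂_RR)` are enforced by tests at
`1e−10`/`1e−12`.

The model exposes the two structural ambiguities analytically: (i) for a
two-state system the cross amplitude carries no information beyond the
two autocorrelations, and (ii) in a static background only
`t_R = 1/(k12+k21)` and the product `p_d x_d(1) x_d(2)` are observable,
so `(p_d, k12, k21)` families along `p_d k12 k21 = const` (at fixed
`t_R` and total fractions) generate identical curves — verified to
`1e−9` in the tests and sampled by the MCMC analysis.

## TCSPC model

The donor decay of a mixture is `f(t) = Σ x_i exp(−t/(τ_D0(1−E_i)))` —
amplitudes weighted by species fractions. Because each species then
contributes photons in proportion to `x_i τ_i`, this expression is
simultaneously the correct shape for a measured photon histogram; a
photon-weighted variant is provided as a comparison utility for the
alternative reading. No IRF convolution by default (ideal simulations);
a Gaussian IRF hook exists. Micro-time range 25 ns, 4096 bins (fits
typically rebin to 256–512). Decay fits profile the scale analytically
each iteration and parameterize fractions through softmax logits for
unconstrained optimization; Poisson weights `√counts`.

Note an identifiability fact quantified during development: a
three-exponential decay fit at 10⁷ counts has 1σ errors of ~0.01–0.04 on
the `E_i` even when started at the truth (χ²ᵣ ≈ 1); the self-recovery
test therefore uses 3×10⁸ counts, where fractions recover to 0.02 and
efficiencies to 0.01.

## Simulator

Photon-level Monte Carlo: point molecules perform free Brownian motion
(diffusion coefficient set by `t_diff = w₀²/4D`) in a periodic box of
4w₀ × 4w₀ × 4z₀ (configurable) around the Gaussian detection profile
`W(r) = exp(−2(x²+y²)/w₀² − 2z²/z₀²)`. Photons are an inhomogeneous
Poisson process with rate `Q₀W(r)`, split green/red by the molecule's
instantaneous state (γ, α applied by thinning), with micro times drawn
from the corresponding exponential decay (donor `τ_D0(1−E)`, acceptor
1 ns) and wrapped at the 25 ns TCSPC range. Dynamic molecules carry an
exact Gillespie trajectory (exponential waiting times — relaxation times
are unbiased by the diffusion step); static molecules keep a fixed
state. The configured time step must satisfy
`dt ≤ min(t_R, t_diff)/10` and defaults to 5–10 µs. Everything is
reproducible bit-for-bit under a fixed seed.

Two deliberate design choices matter for quantitative work:

* **Stratified composition.** Molecule categories (dynamic vs static,
  and static states) are assigned by largest-remainder apportionment,
  not Bernoulli draws: with a few tens of molecules, binomial
  composition noise would otherwise dominate every amplitude comparison
  against the analytic models.
* **Closed-box baseline.** A fixed molecule number in a periodic box
  suppresses number fluctuations, adding an exactly known constant
  `−1/n_molecules` to every correlation curve, and box re-entry adds a
  small positive tail at lags approaching the box-crossing time. FCS
  fits therefore carry an additive offset parameter (fixable to the
  known value), and fits crop lags ≳ 4·t_diff.

What the generator emulates: diffusion-limited observation windows,
shot noise, channel crosstalk/detection corrections, state exchange on
µs–ms timescales, burst statistics. What it does not: dye photophysics
(triplet blinking, bleaching), linker dynamics, background photons,
afterpulsing, saturation. Tests passing on this generator validate the
estimators under those idealizations, not instrumental artifacts.

Burst search: single-channel-sum sliding window (≥ 5 photons within
500 µs), minimum 60 photons per burst.

## Dynamic PDA

For a window of length `T` with `F` detected photons, the red count is
`Bin(F, ε(E))` conditional on the window's mean efficiency `E`, whose
distribution mixes static point masses with the two-state occupancy
distribution, weighted by `p_d`. The photon-number distribution is taken
empirically from the data windows and stratified into ≤ 60 quantile
groups; the binomial kernels (and their mapping into efficiency bins,
501-point E grid, 40 bins) are precomputed once per dataset so each
model evaluation is a handful of matrix–vector products. Fitting
minimizes the summed Pearson χ² over all window lengths with
multi-start Nelder–Mead plus a refinement pass.

Windows should be cut **within bursts** (both cutting modes exist):
slicing the raw stream includes molecule-absent stretches and partial
transits that broaden the histograms beyond the model. Concentration
matters too — window histograms assume one molecule per window, so PDA
inputs should be simulated/measured dilute (mean occupancy ≲ 0.2;
coincidences otherwise transfer static weight into the dynamic
component). Under those conditions the fit recovers `p_d` to ±0.03 and
rates to ~10–20 % low (the intensity-weighted sampling of the state
trajectory shortens the effective window, a known mild bias of
window-PDA).

## Filtered-FCS

Species filters are weighted least-squares estimators over the
(channel × 64 micro-time bins) histogram: `F = (PᵀDP)⁻¹PᵀD`,
`D = diag(1/W_total)`, giving exact unbiasedness `F·P = I`. Patterns
come from the model decays (species parameters known in simulation); a
sub-ensemble-derived pattern path exists for real data. Collinear
patterns (identical lifetimes) raise an error naming the pair; nearly
degenerate ones warn with the condition number.

Species correlations are computed by the same multi-tau engine with
per-photon filter weights. The standard analysis is a global fit of all
n² curves with a shared relaxation-time set and diffusion time and free
amplitudes per curve. Connectivity is read from two signatures: a pair
with no direct or indirect exchange shows zero kinetic amplitude, and a
pair connected only through an intermediate shows a *delayed* rise —
quantified here by the half-rise time of the fitted kinetic factor,
which for the 5 ms⁻¹ linear chains is ~4× larger for the indirect pair
(47 µs vs 214 µs analytically). At the very shortest lags filtered
curves are noisy; fits start at ~8–10 µs.

## Global TCSPC+FCS fit

The objective is the sum of squared weighted residuals of one decay
histogram (Poisson σ) and the four color curves (block-wise σ from 16
time blocks, floored at 10 % of the per-curve median because the block
estimate systematically underestimates correlated long-lag noise). The
microscopic parameters are the species efficiencies, the exchange-rate
pair of one dynamic scheme, two static fractions, `p_d`, `t_diff` and
`N`; optionally each curve carries a free additive baseline and a
bounded (0.8–1.25) multiplicative amplitude calibration. The calibration
factors absorb the few-percent amplitude uncertainty of a finite
measurement (finite transit counts) which would otherwise leak into the
relaxation time; with them, the recovered `k12+k21` is within 10 % of
truth across seeds for the reference two-state mixture.

Optimization is bounded least squares on the residual vector with
Latin-hypercube multi-start (default 16). Posterior sampling uses the
affine-invariant ensemble sampler on `exp(−χ²/2)` with uniform bounds
(library default 64 walkers × 5000 steps, 20 % burn-in; tests use
smaller, documented sizes). Scheme selection is deliberately *not*
automated: per-scheme fits expose the χ² degeneracy, and the workflow
requires the FRET-line evidence (or an external `p_d`/`x_d` estimate,
via the resolver helpers) to pick the branch. The physically admissible
segment of the `(p_d, k12)` manifold is bounded by nonnegative static
fractions; the MCMC analysis spreads over exactly that segment with flat
χ².

## Workflow

`run_workflow` mirrors the three-step procedure: (1) burst histogram +
static-line classification + peak finding, color-FCS relaxation count
(χ² improvement threshold 20 %), sub-ensemble decay component count, and
candidate-scheme admission by distance of the dynamic population from
each binary dynamic line; (2) rates from `t_R` plus the line-position
occupancy, optional PDA; (3) re-simulation with the inferred model and a
Kolmogorov–Smirnov comparison of efficiency histograms. Every candidate
carries the evidence that admitted or eliminated it.

## Reference simulations and problem sizes

The seven reference scenarios (fixtures 1–7) use species LF/MF/HF at
E = 0.2/0.5/0.8 (MF′ = 0.35), τ_D0 = 4 ns, symmetric 5 ms⁻¹ exchange
(6.3/3.7 ms⁻¹ for the asymmetric case), diffusion times 5 ms (1–3) and
3.8 ms (4–7), dynamic fraction 0.4 and equal static fractions. The
E values, brightness (500 kHz at focus) and box geometry are package
defaults chosen for ideal single-molecule statistics, not published
values. Test problem sizes are chosen so each conclusion is comfortably
inside its tolerance at desk scale: 20–45 s streams with 30 molecules
for FCS-grade data, an 80 s dilute stream (box 16w₀, occupancy 0.16)
for burst/PDA-grade data, 10⁵-trajectory Gillespie oracles, 24-walker ×
400–800-step MCMC.

## Known limitations

* Occupancy theory (and hence dynamic PDA) covers two-state exchange
  only; multi-state windows would need the full propagator treatment.
* The amplitude calibration factors in the global fit trade a small loss
  of amplitude information for robustness of the relaxation time; with
  perfectly calibrated data they can be fixed at 1.
* The closed-box simulation baseline is an artifact of the generator,
  not of real measurements; fits expose it as the additive offset.
* Window-PDA rate estimates are biased low by ~10–20 % at windows
  comparable to the transit time.
* Burst-wise lifetime estimation ignores the TCSPC wrap-around
  correction (negligible for τ ≪ 25 ns).
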