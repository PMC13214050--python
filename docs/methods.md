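# Methods

## Model and assumptions

`agekin` analyzes wash-out labeling of metabolic systems assumed to be in
dynamic steady state: pool sizes, fluxes and (under balanced exponential
growth at rate μ) per-volume composition are constant over the experiment.
The labeled and unlabeled variants of the tracked molecule must be
metabolically indistinguishable. Under these assumptions the labeled
fraction f(t) equals one minus the cumulative distribution of the metabolic
age A of the observed molecules, which is the identity every estimator in
the package builds on. Step-up curves are handled by complementation
(1 − f), which maps them onto the same theory.

Four families of quantities are computed, all in minutes / per-minute:

* **ages** (mean age Ā = ∫f dt, half-life = median age): invariant under
  growth, robust to noise because they integrate the curve;
* **decay rates** (κ̄ = −f′(0) − μ; age-resolved κ(A) = −f″/f′ − μ):
  growth enters by subtraction because growth dilution and decay are
  competing exit routes from a fixed reference volume;
* **residence times** (survival 1 − P_T(t) = e^{μt} f′(t)/f′(0)): the
  entry-to-decay time of a particle; growth-dilution "exits" do not destroy
  particles, hence the e^{μt} reweighting;
* **residence time of the living** L (PDF (e^{μt}−1)(f″+μf′)/μ, reducing
  to t·f″ at μ = 0) and its remainder L_r (mean ∫e^{μt}f dt), with
  L̄ = Ā + L̄_r, so L̄ = 2Ā exactly for non-growing systems.

Slope-dependent quantities are intrinsically noise-sensitive; the
age-conditioned variants κ̄_a = −f′(a)/f(a) − μ and
T̄_a = a + ∫_a^∞ e^{μt}f′ dt / (e^{μa} f′(a)) avoid the earliest time
points (default conditioning age a = 60 min, configurable). The subtraction
of μ from the conditioned escape rate is a convention of this package,
chosen so that κ̄_a measures decay only; it is validated against the
particle simulator (cohort splitting of decay vs dilution exits), and the
total escape rate is exposed alongside.

## Numerical choices

**Derivatives.** f′ and f″ on a discrete grid are estimated by local
quadratic least squares over a sliding 5-point window (shifted, and raised
to cubic, at the grid edges, where one-sided quadratics carry O(h) bias).
Raw finite differences are never used. The initial slope f′(0) comes from a
forward quadratic through the first three samples; it is declared "flat"
(delayed input; rate-type parameters undefined) below 3 × noise_sd / span
of those samples.

**AUC tail.** The mean age integrates the sampled range by trapezoids and
adds an analytic tail f(T)/r, with r a log-linear fit to the last three
positive samples ("exponential" policy, the default — finite sampling
otherwise biases Ā down). A "truncate" policy is available; a non-decaying
tail under the exponential policy is an error rather than a silent guess.

**Noise tolerances.** All diagnostics are 3σ decisions against a declared
per-sample noise SD (default 0.01 fraction units), with the noise
propagated into each statistic (a between-sample difference has SD σ√2; a
secant-slope contrast propagates the spans) and a Šidák correction holding
the per-curve family-wise false-fire level at the 3σ point when many
intervals are scanned. The nonconvexity scan compares secant slopes over
anchor triples — evenly spaced anchors plus a geometrically spaced early
block, since delay signatures live at short times. Negative densities
produced by noise are clipped to zero with a warning, never silently.

**Compartmental models.** The state-transition matrix M stores contributed
turnovers: M[i, j] (i ≠ j) is the flux j→i divided by the receiving pool
size s_i, and the diagonal is minus the total influx turnover, so ḟ = M f
with unlabeled external feed. Mass balance requires Mᵀs + μs ≤ 0
componentwise, equivalent to all eigenvalues of M having real part ≤ −μ;
the boundary (equality) is accepted because nondegraded pools — whose
wash-out is pure growth dilution e^{−μt} — sit exactly there. Propagation
e^{Mt}1 uses the eigendecomposition (sum of exponentials) when eigenvalues
are distinct and the eigenvector basis is well conditioned (condition
number < 10⁸), else Padé scaling-and-squaring; repeated-eigenvalue chains
exercise the fallback. Closed forms: Ā = −sᵀM⁻¹1, κ̄ = −sᵀM1 − μ,
T̄ = −sᵀM(M+μI)⁻¹1 / (sᵀM1), L̄_r = −sᵀ(M+μI)⁻¹1, half-life by Brent
root-finding on the system curve; the growth forms are cross-checked
against numerical quadrature in the tests. Validation tolerance is 1e−9
relative; curve-reconstruction checks use 1e−6 absolute.

**Delayed-input composition and reduction.** With a single-source input,
f = f° − (ḟ° ∗ f_r); the convolution is evaluated by trapezoid quadrature
on an internally refined uniform grid, with the error estimated by
comparing two refinement levels (too-coarse grids are an error, not a
warning). Reduction removes unobserved rows/columns of M and renormalizes
the remaining sizes; reduce-then-propagate equals deconvolution of the
composed curve on serial test models, and mean ages are additive.

**Model templates.** The fitting templates place a serial input chain
(0–3 states, rate per state, each > μ) upstream of 1–3 parallel protein
pools (decay rate ≥ 0 each, sizes on the simplex) fed through an
instantaneous zero-size mixer that contributes no age. Input-state sizes
are not free parameters: the observed (pool-weighted) curve is independent
of them, so they are derived from flux balance with zero decay in the
chain, which keeps every assembled template exactly mass-balanced. The
observed curve of this lower-triangular system is evaluated as an explicit
sum of exponentials (stage recurrence), falling back to the matrix
exponential near rate collisions.

**Fitting.** Nonlinear least squares (scipy trust-region reflective) over
unconstrained transforms — log rates (input rates as μ + e^x), stick-
breaking pool fractions — bounded at |x| ≤ 14 against overflow, with 8
seeded Latin-hypercube multistarts spanning rates 10⁻⁴–1 min⁻¹. Parallel
pools are canonicalized by descending decay rate to resolve label
switching. BIC uses the Gaussian unknown-variance convention
n·ln(RSS/n) + k·ln n with RSS floored at n·(10⁻⁶)² so noise-free synthetic
fits stay finite; absolute BIC values are convention-dependent and the
default poor-fit cutoff (−50) should be read qualitatively. Near-ties
(ΔBIC < 2) resolve toward fewer parameters. Note that at realistic noise
(σ = 0.01, 12 time points) the individual rates of a 2-pool fit carry
30–40 % sampling error while the reduced mean age is recovered within a few
percent — the integral quantity, not the rate decomposition, is the robust
deliverable, and the test suite asserts exactly that.

**Bootstrap.** Residual resampling: fitted residuals are drawn with
replacement onto the fitted curve, clipped to [0, 1], and refit (base
solution plus two fresh starts). Reported per quantity: mean, SD and
CV = SD/mean, only when the quantity is defined in ≥ 80 % of resamples;
summaries with > 20 % refit failures are flagged unreliable, and CV ≥ 1
marks a parameter as not robustly quantified.

**Workflow defaults.** Reference proteins: among the 1000 most abundant
species (configurable), drop BIC > −50, keep the oldest 5 % by fitted
observed mean age — degradation only lowers mean age and a shared input
delay shifts all ages uniformly, so the oldest species are the nondegraded
candidates at any delay. The input chain is fit once per dataset/condition
on the abundance-weighted mean reference curve (direct and 1/2/3-state
candidates, BIC-selected) and never refit per species. Growth comes from
the log-linear slope of the biomass series. A naive benchmark (log-linear
single-exponential fit) is included to quantify the bias it incurs on
delayed-input data: it overestimates mean ages, beyond the growth-dilution
limit 1/μ for slow species.

## Synthetic data and the particle oracle

The generator emulates a dynamic-SILAC proteome: per-species compartmental
models sharing one input chain (default 2 states at 0.02 and 0.05 /min,
mean input age 70 min — a precursor delay of roughly an hour), ~10 %
two-pool species with well-separated rates, ~5 % nondegraded species
(biased toward high abundance, as housekeeping proteins are), one-pool
decay rates log-uniform on 5·10⁻⁴–2·10⁻² /min, growth at 0.005 /min,
additive Gaussian noise (default SD 0.01) clipped to [0, 1] with clip
counts recorded, log-normal abundances, and a noisy exponential biomass
series. What it does **not** emulate: peptide-level sampling, missingness,
ionization effects, replicate structure beyond i.i.d. noise, or
non-steady-state biology — so passing recovery tests demonstrates
correctness of the estimators under the stated noise model, not robustness
to mass-spectrometry artifacts.

The particle oracle simulates individual molecules through the continuous-
time Markov process a model defines: entries Poisson over a stationarity
window (intensity ∝ e^{μu} under growth, burn-in 20/|slowest eigenvalue|),
jumps by contributed turnovers, death by decay only; an independent Exp(μ)
dilution clock attributes fixed-volume exits. It shares no code with the
analytic formulas and provides the empirical age / residence-time / RTL
distributions the tests compare against (KS tests at α = 0.01, n = 10⁵
particles). Randomness uses one root seed per call with numpy Generator
streams; identical seeds give bit-identical outputs everywhere, including
fits and bootstraps.

## Problem sizes

Default test and acceptance runs use 12 time points to 480 min per curve,
50-species proteomes, 40–200 bootstrap resamples and 10⁵ oracle particles —
sizes at which every statistical claim in the test suite is already stable.

## Known limitations

* Non-steady-state dynamics are detected (nonmonotone flag) but not
  modeled.
* Compartment counts are capped at 12; beyond ~6 fitted states the
  templates are practically unidentifiable from single curves.
* The age-conditioned growth convention (μ-subtraction) follows this
  package's derivation; other conventions (reporting total escape) are
  accommodated via the exposed escape rate.
* Absolute BIC thresholds transfer across datasets only qualitatively.
* The flat-slope threshold scales with the span of the first three samples;
  for noise-free synthetic curves the caller should declare a
  correspondingly small noise SD.
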