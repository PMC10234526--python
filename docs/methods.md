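# Methods

## The model

`shadownoise` studies how the architecture of *shadow enhancers* — groups of
enhancers that regulate the same gene with overlapping activity — shapes two
performance objectives of transcription: **noise**, the stationary coefficient
of variation of mRNA copy number, CV = σ_R / E[R], and **fidelity**, the
stationary Pearson correlation Corr(T, R) between a transcription factor's
free copy number and mRNA.

Every system is a mass-action chemical reaction network over three kinds of
species:

* free transcription factors T₁, T₂ (produced in bursts of fixed size n_m at
  rate β₁/γ₁, degraded linearly at β₋₁/γ₋₁);
* mRNA R (degraded at α);
* enhancer occupancy states. A k-site enhancer is one conserved unit carrying
  exactly one copy spread over its 2^k bound/unbound patterns. A TF binds an
  empty site bimolecularly at kon of its type and unbinds at koff.

Transcription depends on the regime:

* **additive** (and its sub/superadditive variants): an occupancy state with
  n bound T₁ and m bound T₂ drives mRNA production at n·r₁ + m·r₂, and
  enhancers contribute independently — so a single enhancer with four bound
  T₁ sites produces exactly as much as four single-site enhancers.
* **subadditive / superadditive**: the same transcription rule, but the
  binding kinetics of every site are shifted linearly with the total enhancer
  count n: kon → kon ∓ n·d₁, koff → koff ± n·d₂ (upper signs subadditive).
  The shift is applied exactly once per network build (a `modulated` guard on
  the parameter set enforces this), and a shift that drives any rate negative
  is a hard error — the linear scheme's known breakdown — never a clamp.
* **saturation**: a single rate r (default r₁) whenever at least one enhancer
  has a bound TF; **synergy**: r only while *every* enhancer is bound.

Default kinetics are the values fitted to *Kruppel* shadow-enhancer imaging
data (β₁ = 0.33, β₋₁ = 2.7, γ₁ = 0.29, γ₋₁ = 3.9, kon₁ = 0.36, koff₁ = 1.8,
kon₂ = 0.19, koff₂ = 1.5, α = 1.96, r₁ = 120, r₂ = 140, n₁ = 4, n₂ = 12), in
one consistent arbitrary time unit; no unit conversions are performed
anywhere. Default modulation coefficients are d₁ = (0.04, 0.02),
d₂ = (0.75, 0.75) for subadditivity and d₁ = (0.01, 0.01), d₂ = (0.4, 0.3)
for superadditivity.

### Representation choices

Occupancy is encoded as one species per occupancy state rather than per-site
indicators; this keeps every propensity mass-action of order ≤ 2, which both
the simulator and the moment machinery rely on. The builder refuses more than
12 sites per conserved unit (2^k state species).

The saturation/synergy transcription rule depends on the *joint* occupancy of
all enhancers and cannot be written as an order-≤2 propensity over
per-enhancer states. For those two regimes the builder therefore enumerates
the joint occupancy space (one conservation group over all enhancers, ≤ 12
total sites). Additive-family systems keep per-enhancer groups, whose state
spaces factorize and stay small.

For which rate and TF the saturation/synergy systems use, only "a single type
of transcription factor" is specified upstream; this package fixes r = r₁ with
T₁ kinetics and exposes the rate as the `saturation_rate` config knob.

## Moment closure

Raw moments E[x_J] up to the truncation order (2, optionally 3) evolve by

d E[x_J]/dt = Σ_r E[a_r(x)·(Π_p (x_{J_p}+s_r[J_p]) − Π_p x_{J_p})],

assembled numerically from stoichiometry/propensity tables into flat
coefficient arrays (no symbolic algebra), so systems with hundreds of moment
ODEs evaluate fast. Bimolecular propensities couple order-N equations to
order-(N+2) raw moments; all moments above the truncation order are closed by
setting the corresponding cumulants to zero (for order 2, the Gaussian
identity E[xyz] = E[x]E[yz] + E[y]E[xz] + E[z]E[xy] − 2E[x]E[y]E[z]; higher
orders are generated from set-partition expansions and cached). Linear
networks close exactly, which the test suite exploits as an oracle.

Stationarity is found by long-time integration (LSODA with the analytic
polynomial Jacobian, windows 0–50, then ×4 per window up to t_max = 10⁴) from
the deterministic initial state (empty enhancers, zero TFs and mRNA), declared
converged when the relative RHS norm ‖f‖∞/(1+‖y‖∞) drops below `tol`
(default 1e−8). A Newton polish
(`scipy.optimize.root`) is applied to the integration endpoint and accepted
only if it stays within 1% of that endpoint and meets the tolerance — the
integration, not the root-finder, selects the root, so the multi-root hazard
of closed moment systems does not arise. Closed systems can also blow up in
finite time at unfavourable kinetics; the solver steps are budgeted and the
state magnitude monitored, turning divergence into an explicit
`NonConvergenceError` that sweeps record as a flagged row. Negative stationary
variances (the classic Gaussian-closure pathology at low copy number) set a
`pathological` flag; metrics refuse such states rather than silently truncate.

### Accuracy

On the single-enhancer single-T₁-site system the exact reference (truncated
master equation, below) gives CV = 2.485 and fidelity = 0.156; order-2
closure yields 2.665 and 0.165 (≈7% and ≈5% off), order-3 closure 2.447 and
0.157. The SSA ensemble agrees with the exact values within Monte Carlo
error. The deterministic closure bias therefore exceeds the Monte Carlo
standard error of practical ensembles (≈0.6% at 200 trajectories): closure
and simulation are compared at the closure-accuracy band (15%), while the
simulator is validated against exact references at 3 standard errors.
Fidelity is computed from the *free* TF copy number (the model's species);
bound TFs are part of the enhancer state.

## Stochastic simulation

The Gillespie direct method, exact for these networks, with the event loop
JIT-compiled via numba when available (the pure-Python fallback runs the same
code). Trajectories are sampled on a regular grid (default dt = 0.5) from the
empty initial state. Stationary statistics combine ensemble and time
averaging over [burn_in, t_end] (defaults 100 and 500; the slowest fixture
relaxation time is ≈0.5, so the burn-in is conservative). Per-trajectory
seeds derive deterministically from a base seed via `SeedSequence`. Standard
errors for means and all derived metrics come from jackknife over
trajectories, i.e. batch means with one batch per trajectory.

## Brute-force oracle

For small networks the stationary law is computed exactly: conserved
occupancy groups are enumerated as such, every unconserved species is capped
at a copy-number bound (default: pilot-SSA mean + 10 SD), and the truncated
generator (reflecting boundary) is solved as a sparse linear system
(≤ 5·10⁴ states). The probability mass on the boundary is reported as a
truncation-quality proxy. Closed-form references cover the Poisson
birth–death process, the bursty birth–death process (mean nβ/δ, Fano
(n+1)/2), and the two-state telegraph promoter including cov(promoter, R).

## Comparative studies

Sweeps evaluate configuration lists deterministically and record every model,
flagging failures instead of dropping them. The default grid enumerates all
55 multisets of per-enhancer site-count vectors with ≤ 4 enhancers and ≤ 4
total sites over two TF types; sweeps equally accept explicit lists. Trend
claims are verified as monotonicity verdicts — the Spearman sign over group
means — never as magnitudes; "independent of" claims pass when the relative
spread is below 1e−3 (deterministic methods) or the Monte Carlo band
(simulation). Enhancer-count series hold total sites fixed at (2, 2), split
over 1–4 enhancers; saturation/synergy series use one single-TF site per
enhancer; the duplication comparison duplicates the one-T₁-site enhancer 1–4
times against the matched splits.

Parameter-robustness runs redraw every rate log-uniformly (kon on [0.1, 10],
r on [10, 1000], everything else on [0.1, 100]; burst sizes rounded to
integers ≥ 1, addressing an integrality question the randomization ranges
leave open) and recompute all verdicts per draw. At extreme kinetics the
closure can diverge; affected models are flagged and the corresponding claims
become untestable for that draw rather than silently passing.

## What the synthetic benchmarks do and do not show

All validation rests on synthetic networks whose ground truth is known
exactly (closed forms, truncated master equation) or statistically (exact
SSA). This certifies the *machinery* — network construction, closure algebra,
integration, estimators — under the fitted *Kruppel* kinetics and randomized
variants. It does not certify that the underlying biological model describes
any particular locus: rates are taken as given, enhancers interact only
through the shared TF pools and the stated regime rules (no repression, no
hub/condensate effects), duplications are exact copies, and TF production is
independent of the gene's output.

## Problem sizes and numerical defaults

| knob | default | why |
| --- | --- | --- |
| closure order | 2 | matches the headline analyses; order 3 available |
| stationarity tol | 1e−8 relative RHS norm | exact-fixture tests pass at 1e−6 |
| integrator | LSODA, rtol = atol = 1e−10 | stiff-capable; below test tolerances |
| SSA ensemble | 200 × t=500, burn-in 100, dt 0.5 | SEs ≈ 0.5–1% of metrics |
| CME bounds | pilot mean + 10 SD | boundary mass ≲ 1e−9 on fixtures |
| grid | ≤ 4 enhancers, ≤ 4 sites | full comparison grid, 55 models |
| robustness draws | 4 | one verdict table per draw |
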