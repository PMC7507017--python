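# Methods

## The smoothing model

Cumulative germination data are modeled as discretizations of a continuous,
nonnegative, nondecreasing germination function on the scoring window
`[a, b]`. For data `(t_j, y_j)` with weights `w_j ≥ 0` the fitted curve
minimizes

```
J_l(s) = (1 − α) ∫_a^b (s^(l)(t))² dt + α Σ_j w_j (y_j − s(t_j))²
```

over splines of degree `k` on a fixed break sequence, subject to
`s ≥ 0` and `s′ ≥ 0` everywhere. The fidelity/roughness tradeoff `α ∈ (0,1)`
plays the role a smoothing parameter plays in penalized regression; `α = 0.5`
weights both terms equally and is the default.

**Basis.** Clamped B-splines: boundary knots repeated `k + 1` times, so with
`m + 1` breaks the basis has dimension `m + k`, forms a partition of unity,
and the spline interpolates its first/last coefficient at the endpoints.
The two standard designs are quintic splines on breaks `{0, 2, 5, 8, 10}`
(10-day experiments) and `{0, 7, 14, 21, 28}` (28-day experiments), both of
dimension 9, with penalty order `l = 1`.

**Constraint encoding.** The derivative of a degree-`k` spline is a
degree-`(k−1)` spline whose coefficients are positive multiples of the
consecutive coefficient differences. Requiring nondecreasing coefficients is
therefore sufficient (not necessary) for `s′ ≥ 0` globally — not merely on a
grid — and together with a nonnegative first coefficient gives `s ≥ 0`. The
cost of sufficiency is mild additional stiffness near steep data, visible as
slight overshoot/undershoot smoothing of step-like records; the benefit is a
guarantee that every fitted curve and every curve reconstructed from stored
coefficients is feasible.

**Solver.** Substituting `b = T g` (`T` lower-triangular ones; `g` the first
coefficient and increments) maps the cone onto the nonnegative orthant. With
collocation matrix `C`, penalty Gram matrix `P = RᵀR` (`R` from a symmetric
eigendecomposition with negative eigenvalue noise clipped at zero) and
weight matrix `W`, the problem becomes

```
min_{g ≥ 0} ‖ [√α W^{1/2} C T ; √(1−α) R T] g − [√α W^{1/2} y ; 0] ‖²
```

solved by Lawson–Hanson NNLS (`scipy.optimize.nnls`). A Tikhonov row block
(`~1e−6` relative) guarantees a unique minimizer in degenerate weighting
schemes; it perturbs well-posed solutions far below all stated tolerances.
The objective is strictly convex on the feasible set because the `l = 1`
penalty's null space (constants) is not in the null space of the weighted
collocation (the basis sums to one), so the minimizer is unique. Feasibility
is asserted at `1e−8` on 2001-point grids and KKT stationarity at `1e−6`
scaled by the gradient magnitude.

**Penalty Gram matrices** are assembled per knot interval with
Gauss–Legendre quadrature using `k − l + 1` nodes, exact for the
piecewise-polynomial integrand of degree `2(k − l)`. The same routine with
`l = 0` yields the basis Gram matrix used for exact L² norms.

**Integration.** The CGI uses the exact B-spline antiderivative by default;
a composed-trapezoid evaluation (10 001 points) is retained as a cross-check
and CLI option, agreeing within `1e−6` for all fixture fits.

## Records and degenerate inputs

Records carry strictly increasing observation days starting at day 0 with a
zero anchor (`y(0) = 0`), cumulative proportions in `[0, 1]`, and the
planted-seed total. Duplicate days are rejected rather than averaged, and
missing scoring days are rejected rather than imputed — the model assumes a
fixed day grid and data cleaning is the caller's job. An all-zero record is
valid: it fits the zero spline, has TG = GI = CGI = 0, and LT50, MGT and CVG
are reported as explicit missing values (NaN, empty CSV cells), never 0.
Cohort analyses can either keep or drop zero-germination accessions
(`drop_zero_germination`), since both conventions occur in practice.

## Indices

* `TG` — final cumulative proportion (reported as a proportion, not percent).
* `MGT` — `Σ n_i t_i / Σ n_i` over per-day counts, in days.
* `CVG` — `100 · Σ n_i / Σ n_i t_i`, percent per day.
* `GI` — `Σ (T − t_i + 1) n_i` with `T` the last scored day (10 or 28);
  defined on count units, so it scales with the planted total, unlike the
  others.
* `LT50` — first scored day reaching half the final level; no interpolation
  by default (matching daily scoring practice), linear interpolation as an
  option.
* `CGI` — `∫ s(t) dt`, bounded by `(b − a) · max s`.

Useful identity used in tests: `GI = Σn_i · (T + 1 − MGT)`.

## Function-on-scalar regression

With all curves in one basis, minimizing the integrated squared error over
functional coefficients is exactly OLS of the curves' coefficient matrix on
the design `[1, x]` — the estimate is invariant to the (positive definite)
Gram weighting because the design acts on rows, not basis columns. Global
`R²` is computed from Gram-matrix quadratic forms, never grid sums;
pointwise `R²(t) = SSR(t)/SST(t)` (equivalent to `1 − SSE/SST` at each `t`
because every pointwise fit includes an intercept) is clipped to `[0, 1]`
for reporting and flagged undefined where the curves nearly coincide
(`SST(t) < 1e−12`). A covariate with variance below `1e−12` (relative) or a
design with condition number above `1e12` sets the `singular` flag and all
R² values are reported missing. Records whose covariate is undefined (e.g.,
MGT of a zero-germination accession) are dropped from that index's
regression only.

## Synthetic data

The generator draws each accession from a Hill-type cumulative curve
`p(t) = c·tᵃ/(bᵃ + tᵃ)` — ceiling `c` (viable fraction), half-time `b`
(days), steepness `a > 1` — with counts sampled as binomial increments from
the not-yet-germinated pool using the conditional hazard
`(p(t) − p(t−1))/(1 − p(t−1))`, which guarantees monotone cumulative counts.
This emulates the sigmoid shape, the sub-unit ceiling and the binomial
scoring noise of real germination trials; it does not emulate inter-replicate
overdispersion, seed-to-seed correlation, scoring error, or non-sigmoid
(e.g., biphasic dormancy-release) curves, so passing tests demonstrate
correctness of the machinery under idealized sampling, not robustness to
those features. Default study-scale choices in tests: 100 seeds (matching
the benchmark records' scale; 25 in the 28-day pathway test), 10 or 28 daily
scores, ceilings 0.2–0.95, half-times 2–18 days, steepness 2–6 — ranges a
germination trial on partially dormant wild material would plausibly span.
Cohort-level power checks use 200 replicates per condition with fixed seeds.

## Benchmark fixture

The 32 embedded hypothetical records (8 scenarios × 4 seed lots, 100 seeds,
10 days) are stored at the printed one-decimal precision without
renormalization, so some totals are 94.8 or 94.5 rather than 95 — the
printed tables carry that rounding, and reproducing published values
requires keeping it. A handful of published index cells are inconsistent
with the defining formulas (printed-rounding and transcription artifacts);
exact comparisons in the tests use only formula-consistent cells, and the
published CGI row is compared by correlation and by absolute tolerance on
selected entries.

The wild-pea 28-day cohort's raw counts are not redistributable;
`load_appendix_s1` reconstructs AGDFs from a supplementary-style B-spline
coefficient CSV (9 coefficients per accession on the 28-day basis, feasibility
re-checked on load, stated CGI column verified within `1e−3`) so that cohort
can be analyzed when the file is available. Tests exercise this pathway with
a synthetic stand-in.

## Known limitations

* `α` and the knot layout are fixed a priori; no cross-validation or
  data-driven knot selection is provided.
* The sufficient-condition cone is a strict subset of all monotone splines;
  fits can be marginally stiffer than the tightest feasible smoother.
* No uncertainty quantification: neither confidence bands for the AGDF nor
  inference on the functional regression coefficients.
* Small cohorts (the four-lot scenarios) make `R²_glob` an unstable
  summary; it is reported for comparability, not inference.
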