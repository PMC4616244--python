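# Methods

## Model

A grid system is a set of m modules with periods λ_1 > … > λ_m and field
widths l_i, in n spatial dimensions, with a coverage factor d (cells
responding at any one location).  The behavioral requirement is a fixed
resolution — the number of distinguishable spatial bins — and the quantity
minimized is the total neuron count.  Everything in the optimization is
dimensionless: only the ratios r_i = λ_i/λ_{i+1}, λ_i/σ_i and σ_i/δ_{i-1}
enter, so the results are independent of the absolute spatial scale, of
the resolution R and of d (these cancel in all normalized cost curves, and
the tests check that they do).

### Winner-take-all decoder

Resolution fixes Π r_i^n while the cell count is d·Σ r_i^n; by AM-GM the
optimum has all ratios equal, and minimizing r^n/ln(r^n) gives r* = e^(1/n).
The integer-m refinement compares m = ⌊ln R⌋ and ⌊ln R⌋+1 on
N = d·m·R^(1/m) (ties resolved toward fewer modules — fewer parts at equal
cost).  The general formulation with range L, accuracy A = c1·l_m and
ambiguity constraint λ_{i+1} ≥ c2·l_i is solved through its KKT conditions:
every multiplier is nonzero, so every constraint binds, giving λ_1 = L, a
common ratio, and the same optimum.  c2 is exposed as an input constant
because the mapping from coverage and tuning shape onto the ambiguity
threshold is model-dependent.

### Probabilistic decoder

The per-module likelihood is a periodic sum of Gaussians; combined with
the running Gaussian posterior it yields a mixture with weights
π_j ∝ exp(−j²λ²/2(σ²+δ²)), centers (Σ/σ)²λj and common width
Σ² = (σ⁻²+δ⁻²)⁻¹.  Its variance gives the sharpening factor

ρ(λ/σ, σ/δ) = (1+δ²/σ²)^{1/2} (1 + (1+σ²/δ²)⁻¹ (λ/σ)² Σ j²π_j)^{−1/2},

a trade-off between central-peak precision (first factor) and side-lobe
ambiguity (second).  In 2D the peaks sit on the lattice generated by a
unit vector u and v = (v∥, v⊥), the per-axis variance convention puts a
factor ½ on the lattice second moment, and the weight exponent uses the
squared lattice-vector lengths.  The symmetric (fixed-ratio) solution
makes ρ equal to the scale factor and the total count
N = c(λ/σ)/ln ρ (1D) or N = c·v⊥(λ/σ)²/ln ρ (2D); results are
independent of the prior width δ_0, which only enters transient terms of
the recursion.

Two conventions deserve note.  First, the 2D neuron count carries the
unit-cell area factor v⊥ (phase count = unit-cell area ÷ field area);
without it the geometry optimization has no reason to prefer the
triangular lattice, with it the triangular lattice is the clear optimum,
consistent with the circle-packing equivalence of the WTA argument.  A
`v_perp`-free variant can be evaluated manually by fixing the geometry,
since at fixed geometry the factor is a constant multiplier that does not
move the optimum over λ/σ.  Second, module lattices are taken mutually
aligned; the mixture composition assumes a common basis.

## Numerics

- **Truncation.**  1D mixture sums run over j ∈ [−K, K], K = 500 by
  default; 2D lattice sums over |n|, |m| ≤ 60.  A tail check flags any
  evaluation whose boundary weight exceeds 1e-12 of the central weight.
  Inside the σ/δ maximization this check becomes a hard floor on σ/δ:
  below the floor the truncated second moment saturates and ρ would be
  spuriously inflated (the apparent ρ → ∞ at small λ/σ and σ/δ is purely
  a truncation artifact; the true maximum is interior).  All reported
  optima are stable to < 1e-6 under K → 2K.
- **Optimization.**  Inner maximization of ρ over σ/δ: coarse log-spaced
  scan (60 points on [max(10⁻³, floor), 10]) then bounded scalar
  refinement, tolerance 1e-9.  Outer minimization over λ/σ: bounded
  scalar search on [2, 30] (1D) / [2.5, 20] (2D), tolerance 1e-6.  Free
  2D geometry: 3×3 coarse scan over (v∥, v⊥) then Nelder-Mead on
  (λ/σ, v∥, v⊥); geometries are canonicalized into v∥ ∈ [0, ½] using
  lattice relabeling symmetry, which the tests verify leaves ρ₂ invariant.
- **Cost curves and intervals.**  ρ_max is monotone in λ/σ, so the
  normalized cost at ratio r inverts it by Brent root-finding and
  evaluates the objective; 5%-excess endpoints are Brent roots of
  cost = 1.05 on either side of the optimum.  The WTA curve is closed
  form and its endpoints come from bisection to 1e-6.
- **Quadrature oracle.**  `delta_oracle` recomputes the posterior width by
  direct numeric integration of the likelihood × prior product (grid step
  σ/30, halfwidth 10·δ_prev, tail mass checked against 1e-10), fully
  independent of the ρ formulas; the two agree to 1e-4 relative across
  the sampled parameter box, and the telescoping property δ_0/δ_m = ρ^m
  holds through the composed quadrature.

Recomputed optima at these settings: 1D ρ* = 2.283 at λ/σ = 9.03
(π_1/π_0 = 1.25×10⁻³); 2D ρ₂* = 1.433 at λ/σ = 5.18 on the triangular
lattice; intervals (1.43, 1.96) WTA and (1.277, 1.659) probabilistic.

## Synthetic data

The generators emulate the statistical structure the analysis assumes,
not any particular data set.

- **Period tables** are geometric progressions λ_1·r^(−i) with
  multiplicative lognormal noise (log-sd = `noise_cv`) and independent
  module dropout, per animal.  Defaults r = 1.65, cv = 0.05, m = 4,
  λ_1 = 100 cm match the modular structure reported for rodent grid data
  (4–5 modules, largest period on the order of a meter, few-percent
  scatter in ratios).  The reanalysis pipeline recovers the generating
  ratio within sampling error; this validates the procedure, not the
  empirical ratio values, whose source tables were digitized from figures
  and are not reproduced here.
- **Spiking populations** are 1D: cells with periodic Gaussian tuning
  (sd = 0.08·λ by default, peak rate 10 Hz, 100 ms windows — typical
  grid-cell firing and a behavioral sampling time), phases tiling each
  period evenly, independent Poisson spike counts, positions on a circle
  of circumference λ_1 to avoid edge effects.  So that every module is
  exactly periodic on the circle, periods snap to λ_1/k with integer k
  nearest the requested progression; realized periods are recorded and
  used in all analytic comparisons (for non-integer r the realized ratios
  deviate from the request — deliberately accepted in exchange for exact
  periodicity).  The per-module likelihood width is predicted by Fisher
  information, σ = (T·ρ_ph·R₀·√(2π)/w)^(−1/2) with ρ_ph the phase
  density; agreement with the fitted width and with the composed
  δ-recursion is within 10% once expected spike counts are ≳ 10 (at very
  low counts the width of the realized posterior exceeds the Fisher
  bound — Jensen's inequality on w/√n — which is a property of the
  regime, not an error).
  2D spiking simulation is not implemented: the analytic 2D theory is
  covered by ρ₂, and a 2D generative model would add a commensurate-torus
  construction without changing what the Monte-Carlo validates.

What passing Monte-Carlo tests show: the δ-recursion correctly predicts
the combined posterior of independent-Poisson populations with uniform
phase coverage, including the onset of side-lobe ambiguity when scale
ratios grow too fast.  What they do not show: robustness to correlated
noise, heterogeneous peak rates, non-uniform phases, or real tuning-curve
shapes — all outside the generator's scope.

## Estimates

Module count m = ln R / ln r^n and neuron count N = m·(1/K)·(λ/σ)² are
exact arithmetic on their inputs; the per-module constant is taken as
exactly 1/K (K = expected spikes per sampling window), the equality that
reproduces the published order-of-magnitude chain R₂ = 10⁴ → m ≈ 10 →
N ≈ 1400 with K = 1/5.  Both the real module count and its ceiling are
returned; the WTA ratio √e is used for the headline m (the two decoders
bracket the estimate: √e gives 9.2, 1.44 gives 12.6).

## Reanalysis conventions

Grouping uses greedy chaining on ascending-sorted periods against the
running group mean with a 20% relative threshold — deterministic and
order-independent after sorting; for pathological inputs (a near-continuum
of periods) chaining can merge what pairwise comparison would split, which
is documented rather than hidden.  The pooled dispersion is reported as a
sample standard deviation (n−1); animals yielding a single scale are
excluded from pooling.  Period-to-field-radius ratios are halved to
period-to-diameter before comparison with the λ/l = e prediction.

## Limitations

- The decoder theory assumes independent noise across cells and modules;
  correlated noise would raise all neuron-count estimates and may shift
  g(d)-type scalings.
- The 2D analysis fixes mutually aligned module lattices; relative
  rotations are not explored.
- 3D is covered only by the scalar ratio e^(1/3); no 3D lattice geometry
  is constructed.
- The mapping between the published λ/σ value (5.3) and ours (5.18)
  differs by ~2%; the published computation's exact numeric settings are
  unknown, and we report what the stated equations yield under the stated
  truncation.
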