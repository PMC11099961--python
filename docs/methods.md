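# Methods

## The inference problem

A metastable escape with Poisson kinetics has exponentially distributed
first-passage times (FPTs) with rate k; the mean FPT (MFPT) is 1/k.
Infrequent metadynamics (iMetaD) accelerates the escape by depositing
repulsive Gaussian bias hills along a collective variable (CV) and
converts each biased FPT back to an estimate of the unbiased time through
the acceleration factor

    τ = Σ_i Δt · exp(β V(s(t_i), t_i)),

a left-Riemann sum of the exponentiated instantaneous bias at the
walker's CV position.  The bias is piecewise constant between
depositions, so the left-Riemann form integrates it exactly; bias
energies are stored in k_B T, making β = 1 internally, and any unit
conversion happens only at I/O.  With nonnegative bias the acceleration
τ/t is ≥ 1.

Two estimators of the MFPT are implemented.

**Whole-sample exponential fit.**  Least squares of the model CDF
1 − exp(−t/τ̄) against the empirical CDF evaluated at the sample points
(plotting positions i/(n+1)), followed by a one-sample
Kolmogorov–Smirnov test of the data against the fitted exponential;
p > 0.05 is the customary reliability threshold.  The KS p-value is
computed from the standard one-sample distribution, uncorrected for the
estimated parameter — the conventional usage for this reliability score,
to be read as a heuristic rather than an exact test.  A
maximum-likelihood variant (τ̄ = sample mean) is exposed as an option;
the two coincide on exactly exponential data.

**Short-time survival fit.**  The empirical survival curve uses
S(t_(i)) = 1 − i/(n+1), which keeps every point's logarithm finite (the
naive i/n rule sends the largest point to −∞); duplicated values each
keep their own rank.  For every candidate cutoff t* among the order
statistics from rank `min_points` (default 5) to n, the curve restricted
to t ≤ t* is fitted by the one-parameter line through the origin,

    k(t*) = −Σ t_i y_i / Σ t_i²,   y_i = log S(t_i),

(normalization fixes log S(0) = 0, so the intercept is not a free
parameter) and scored by the squared ordinary Pearson correlation of
(t_i, y_i).  The best-scoring cutoff wins; exact ties go to the largest
t*, using the most data.  All cutoffs are evaluated in O(n) via prefix
sums, and the closed-form slope is the exact minimizer of the
through-origin least squares (the test suite cross-checks it against
brute-force 1-D minimization).  Degenerate samples (all values equal)
and non-positive fitted rates raise typed errors rather than returning
numbers.

**Bootstrap.**  Uncertainty is summarized over batches resampled with
replacement: quartiles, and whiskers at the most extreme estimates
within 1.5·IQR of the quartiles (box-plot convention).  Batches on which
an estimator fails are excluded and counted, never silently dropped.
**Speedup** is the unbiased MFPT divided by the mean biased
(unrescaled) FPT.

## The simulator

A single particle of mass 40 a.u. moves on the two-dimensional
Wolfe–Quapp two-state surface in the NVT ensemble at 300 K, integrated
with the BAOAB splitting of the Langevin equation at a 1 fs timestep and
a friction (damping rate) of 0.01 fs⁻¹.  BAOAB is chosen for its
configurational accuracy among the standard Langevin splittings; with
zero friction the noise and drag vanish and the scheme reduces exactly
to velocity Verlet (the suite checks 10⁻⁴-level energy conservation and
3%-level equipartition).  Initial velocities are Maxwell–Boltzmann.

The surface is the modified Wolfe–Quapp quartic
u⁴ + v⁴ − 2u² − 4v² + uv − 0.3u − 0.1v (energies in k_B T, distances in
nm) expressed in a lab frame fixed by a rotation (11.06°) and isotropic
dilation (×1.0895) chosen so that the global minimum sits exactly at
(1.564, −1.334) nm.  The second minimum then falls at (−1.512, 1.353) nm,
inside the committor-style stopping region x < −1.4 nm ∧ y > 1.0 nm,
and the saddle lies near the origin with a 6.78 k_B T barrier from the
global minimum — which at these parameters puts the unbiased MFPT on the
100 ns scale.  Trajectories start at the global minimum and stop when
the target predicate holds, checked every step by default (configurable
stride); runs that exhaust `max_steps` are returned as censored, flagged,
and excluded from inference with a logged count.

Metadynamics bias acts on a 1D CV: the projection of (x, y) onto a unit
vector.  The default ("good") CV is the interwell axis — the unit vector
from the global minimum to the second minimum — which cleanly separates
the metastable states; rotating it by an angle θ degrades it
continuously.  Hills are Gaussians of width σ = 0.1 nm and bare height
h₀ = 0.5 k_B T, tempered by the well-tempered rule
h = h₀·exp(−V(s)/((γ−1) k_B T)) with bias factor γ = 5, deposited every
`deposition_period` steps (the default 10⁵ steps is a 10 ns⁻¹ deposition
rate at 1 fs; the CLI converts rates in ns⁻¹ and rejects non-integer
periods).  The bias and its derivative are accumulated on a uniform grid
(0.01 nm spacing over [−4, 4] nm by default) and looked up at the
nearest node, with boundary nodes used outside the grid — mirroring a
gridded PLUMED bias.  Hills deposited at a step boundary act from the
following step onward, and the per-step bias series records the value
after any deposition at that step; the series is recorded every step.

Identical (configuration, seed) pairs give bit-identical trajectories;
the end-to-end pipeline derives every stream from one master seed via
`SeedSequence` spawning and records it in the run manifest.

## Synthetic data

Two generators give the inference layer known ground truth without any
simulation.

*Clean kinetics*: i.i.d. exponential FPTs with rate k.

*Breakpoint inflation*: draw T ~ Exp(k); values ≤ t* pass through
unchanged, values beyond have their excess stretched,
t* + (T − t*)·A, with A = max(1, LogNormal(μ, σ_A)).  Below the
breakpoint the distribution is exactly the target (truncated)
exponential; beyond it the tail is stochastically inflated.  Clipping A
at 1 means corruption can only lengthen a rescaled time, matching
overdeposition physics.  The closed-form mean
1/k + (E[A] − 1)·e^(−k t*)/k (with the clipped-lognormal mean E[A]
evaluated via the normal CDF) serves as an independent oracle.

Default parameters are the reference study conditions: k = 1/110 ns⁻¹,
t* = 21 ns, and strong inflation μ = 2, σ_A = 1 (E[A] ≈ 12), chosen so
the whole-sample fit overestimates the MFPT roughly tenfold — the regime
where short-time inference is needed.  What this model emulates is the
*distributional* signature of overdeposition (correct short-time
statistics, slower-than-exponential tail); it does not model the bias
accumulation process itself, trajectory-to-trajectory correlations, or
censoring.  Tests passing on it therefore establish the estimator's
statistical behaviour, not the fidelity of any particular simulation.

## The scaled-down validation study

Brute-forcing the full surface (MFPT ~10² ns at 1 fs) is a
cluster-scale exercise, so end-to-end validation runs on a depth-reduced
variant: every energy — surface and hill height alike — multiplied by
0.8, preserving the hill-to-barrier ratio of the reference setup.  The
factor was set by two requirements.  First, brute force must be cheap:
at 0.8 the barrier is 5.42 k_B T and the measured unbiased MFPT ≈
7.5 ns, so hundreds of unbiased trajectories integrate in well under a
minute each batch.  Second, the variant must keep the Poisson character
the inference assumes.  The diffusive transit between the wells
(D = k_B T/mγ ≈ 0.006 nm²/ps over ~3 nm, i.e. ~0.5 ns) does not shrink
with the barrier, so depth reduction erodes exponentiality from below:
at a 0.4 factor the MFPT (~2.4 ns) is only ~5 transit times and the KS
test rejects exponentiality outright, while at 0.8 the transit is ~6% of
the MFPT and KS p-values at n = 200 sit comfortably above 0.05.  The
same lag biases a through-origin short-time fit upward by O(lag/t*), so
validation uses slow deposition rates (5 and 10 ns⁻¹, the regime in
which the rescaling premise holds on this variant, with speedups around
2), 200 brute-force and 150 biased trajectories per rate, and bootstrap
batches of 50 (the same 1:3–1:5 batch-to-sample ratio used at full
scale with 200-sample batches from 1000 trajectories).  The acceptance
check asks the brute-force MFPT to fall inside the short-time
estimator's bootstrap IQR at both rates.

## Numerical choices and edge cases

* Hills are truncated 6σ from their center when added to the grid
  (exp(−18) ≈ 10⁻⁸ of the height).
* `deposition_rate_to_period` rejects rates that are not a whole number
  of timesteps rather than rounding silently.
* The whole-sample CDF fit minimizes over τ in [mean/200, 200·mean]
  with a bounded scalar minimizer; exact data recover the mean to
  optimizer tolerance.
* Candidate cutoffs at tied FPT values collapse to the last index of the
  tie run, so a cutoff always includes every point ≤ t*.
* Zero or negative FPTs are rejected at `FPTSample` construction;
  censored trajectories raise on rescaling and are excluded (and
  counted) by the pipeline.
* COLVAR-style parsing is header-driven (any column order), infers Δt
  from consecutive times, and rejects non-uniform spacing and negative
  bias with line numbers.

## Known limitations

* The cutoff selection maximizes R², which on mildly contaminated data
  with few samples (≲100) can pick a too-large t* and inherit some tail
  bias; with ~10³ samples it localizes at or below the true breakpoint
  (never meaningfully above it, the harmful side).
* The short-time fit inherits the Poisson assumption: systems whose FPT
  distribution deviates at short times (e.g. a non-negligible transit
  lag, as on strongly depth-reduced surfaces) bias it upward.
* The KS reliability p-value ignores parameter estimation and is
  heuristic.
* The simulator is a model-potential engine: one walker, one biased CV,
  no molecular force fields or engine integration beyond file-format
  compatibility.
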