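# Methods

This note records the model assumptions, the numerical and design
choices made where the procedure was genuinely open, what the synthetic
cohorts do and do not emulate, and the known limitations.

## Surprisal analysis

The decomposition applies the SVD directly to the natural-log expression
matrix (genes × samples), with no mean-centering: `ln X = G λᵀ`, gene
weights `G` orthonormal, amplitudes `λ = V Σ` so each amplitude column's
norm is a singular value. Diagonalizing the two covariance matrices of
the log data yields the same subspaces; the direct SVD is a single,
numerically safer code path and is what we implement.

*Sign convention.* The SVD leaves each component's sign free. We flip
each (G, λ) column pair so the column sum of λ is positive; if that sum
is exactly zero, the gene weight of largest magnitude is made positive.
For nonnegative log data this makes every steady-state amplitude
λ₀(k) > 0. Process amplitudes (α ≥ 1) are reported signed; only their
magnitudes against the error limits decide significance.

*Noise floor.* σ is the mean across the most stable transcripts (lowest
per-gene SD of log expression across samples; `fraction` of the gene
list, default 1%) of those SDs. The estimator presumes that the most
stable transcripts' variability is measurement noise — i.e. that some
transcripts carry no biological signal but full technical noise. On a
constant matrix σ = 0 and the estimate is flagged degenerate.

*Error limits.* For each process α the threshold is mean + 2·SD of
`max_k |λ_α(k)|` over `n_surrogates` (default 100, seeded) decompositions
of i.i.d. Gaussian(0, σ) matrices of the data's shape. This
operationalizes "indistinguishable from measurement noise" directly and
is reproducible under a seed. Thresholds are per-α. With σ = 0 the
limits collapse to a machine-precision floor.

*Number of significant processes.* The smallest m such that the
rank-(1+m) reconstruction leaves at least 95% of residual entries within
2σ (both constants configurable). Note the headroom of this rule is
thin by construction: pure Gaussian residuals put 95.45% of entries
within 2σ, so the rule only behaves when σ is estimated essentially
without bias — see the synthetic-data section for the consequences.

## State-space

The state-space follows the standard eigengene construction: genes are
mean-centered across the training cohort (normal + primary AML), the SVD
of the samples × genes matrix gives principal components `PC = U Σ` and
eigengenes `V`, and the retained component is the one maximizing cluster
separation — the gap between the maximum normal coordinate and the
minimum AML coordinate after orienting the AML mean to the right. Ties
between components go to the lower index. Held-out samples are projected
by subtracting the stored training mean and multiplying by the chosen
eigengene.

*Mutual information.* The gene ranking uses the k-nearest-neighbour
mixed continuous/discrete estimator (digamma form) with k = 3 by
default; distance ties are broken by a seeded jitter of 1e-10 times the
signal scale; a constant signal returns exactly zero; negative estimates
are clipped at zero with the raw value retained. The estimator is
rank-based and hence invariant under monotone transforms of expression.

*Selection loop.* Genes are ranked by MI once; while the clusters
overlap, the lowest-MI genes are dropped (`batch_step` per iteration,
default 1 — a batched step costs O(n/step) SVDs instead of O(n²) work
and reaches the same kind of separated fixed point) and the state-space
is rebuilt. The loop stops at positive separation or at a floor gene
count, in which case the retained set is returned flagged unseparated —
the correct outcome for cohorts where selection cannot improve
separation and all genes should be used.

## State-transition model

The quasi-potential is the integral of
`∇U_p = scale·(x−c1)(x−c2)(x−c3)` with the constant fixed by
U_p(c1) = 0, so well energies compare directly and the Boltzmann
exponent is −U_p(c3).

*Critical points.* c1 and c3 are the k-means (k = 2, 10 seeded restarts)
centroids of the 1-D coordinates, designated by which cluster holds the
majority of normal-labelled samples. The observed occupancy ratio is
taken from the k-means cluster counts (available before c2 exists). c2
minimizes `|ln(ratio) − (U_p(c1) − U_p(c3))|` over a 1000-point interior
grid with bounded refinement; grid ties resolve toward the midpoint, and
a residual above 1e-3 warns that no interior barrier matches the ratio
at this scale.

*Scale and temperature.* The cubic's prefactor is not identified by the
data, so the default rescales to the well separation: scale =
64/(c3−c1)⁴, which sets the symmetric barrier height to exactly one
energy unit and keeps log-occupancy-ratios of magnitude up to ~5
attainable inside (c1, c3). The diffusion coefficient β⁻¹ defaults to
the stationary Gaussian approximation at the normal well:
β⁻¹ = U_p''(c1) · s², with s² the sample variance of the c1 cluster.

*Assignment.* Each sample goes to the nearest critical point; distance
ties involving c2 resolve to c2, a conservative flagging of the unstable
state.

*Dynamics.* The Langevin engine is Euler–Maruyama with a stability
guard dt·max|U_p''| < 0.5 over the padded well region. The
Fokker–Planck engine is a Chang–Cooper exponentially fitted finite
volume scheme on a uniform grid with reflecting (zero-flux) boundaries
and half-width boundary cells, so the conserved cell mass equals the
trapezoidal mass exactly and the discrete stationary state matches the
Boltzmann two-point ratios. Time stepping is explicit with
dt = 0.4·h²/(2β⁻¹ + max|drift|·h) by default; a user dt above the bound
is rejected. A drift override turns the solver into a generic 1-D
advection–diffusion integrator (used to validate against the analytic
Ornstein–Uhlenbeck solution).

*Pseudotime.* Empirical mid-ranks of a marker gene's expression rescaled
to [0, 1] (KIT-like usage). The marker must be non-constant and is
checked for normal/AML difference by a Welch t-test; an uninformative
marker warns rather than errors, since rank pseudotime remains defined.

## FEC and barcodes

FEC/RT sums linear-scale expression times the deviation terms over the
full transcript set — the error limits gate processes, not genes — and
only over processes within the significant set whose amplitude in that
sample exceeds its limit. An empty active set gives FEC exactly 0. Both
signed and absolute values are kept; group statistics use absolute
values. Barcodes discretize strictly: an amplitude exactly at the limit
codes 0. The catalogue groups exact ternary strings and orders by count,
then lexicographically. Critical-point comparisons use one-way ANOVA on
|FEC| with pairwise Welch t-tests, reported raw and Holm-adjusted;
groups with fewer than two samples are excluded with a warning.

## Synthetic cohorts

The generator plants `ln X = G Λᵀ + E` and exponentiates. Defaults are
the package's study conditions: 1000 genes × 120 samples, three
unbalanced processes, Gaussian log-noise of SD 0.25 (~25%
multiplicative), group fractions 0.4/0.2/0.4 for normal/transition/AML,
steady-state amplitude 100 (log expression spanning roughly 0.7–7
natural-log units), and a 4% stable-transcript subset.

What it emulates, and how:

- **Invariant steady state.** λ₀ is exactly constant; the recovered
  steady state varies below 1% CV under default noise.
- **State-coupled process.** Process 1 has amplitude 0/m/2m in
  normal/transition/AML. Its cohort mean is absorbed by the steady-state
  component, so the analysis sees −m/0/+m: groups order along the
  state-space with the transition cohort at the centre, normals fall in
  the c1 well, AML in c3, transition at the barrier.
- **Patient-specific subsets.** Processes 2..P are active in all
  transition samples (mutually orthogonal Walsh sign patterns) and in
  one AML "subtype" each (sign-balanced halves; subtype sizes halve:
  1/2, 1/4, … of the AML cohort, remainder carrying process 1 only).
  Amplitude columns are orthogonalized exactly within their supports,
  and an amplitude ladder (30σ/32σ/26σ…, subtype side at 75%) keeps
  singular values separated — without distinct singular values the SVD
  could only recover rotated mixtures. The set of distinct planted
  barcodes is therefore a deterministic ground truth.
- **Stable transcripts.** A gene subset with no process loadings and
  full technical noise — their SD *is* the noise floor, which is exactly
  why the stable-transcript estimator works. The 4% default (40 genes at
  desk scale) keeps the floor estimate's sampling error (~1%) inside the
  thin headroom of the 95%-within-2σ significance rule; 1% of a
  45k-transcript genome-scale panel would give the same stability.
  A `stable_noise_factor` allows genuinely lower-variance subsets, but
  note that feeding the significance machinery a floor far below the
  bulk noise makes every reconstruction fail the within-noise test — the
  estimator and the generator must agree on what "stable" means.
- **Process gene weights.** Two-level loadings on disjoint per-process
  gene blocks: up on the top ~30% of the block by steady-state
  expression, down on the rest, balanced to stay exactly orthogonal to
  the steady-state profile. Every gene carries a bounded loading (no
  accidental noise-floor genes), and because expression is exponential
  in the profile while the balance is linear, each process moves
  abundant transcripts coherently — giving a structurally nonzero FEC
  contribution per process, as real unbalanced processes have. The
  pseudotime marker gene sits in process 1's block with a boosted
  positive loading.
- **Pseudocount.** Generated expression has no zeros, so analysis
  pipelines on synthetic data use a tiny pseudocount (1e-6) to keep the
  planted log-linear structure; the dataio default of 1.0 is for real
  count-derived matrices with zeros.

What it does **not** emulate: count-level (negative binomial) noise,
batch effects, isoform structure, gene–gene correlation beyond the
planted processes, library-size artefacts, or unit heterogeneity across
cohorts (TPM vs FPKM is treated as upstream). Passing tests on these
cohorts show the machinery recovers planted structure under realistic
noise; they do not certify behaviour under real RNA-seq artefacts.

## Problem sizes and numerical tolerances

Simulation-based checks use sizes chosen to make their Monte-Carlo error
small relative to what they assert: parameter recovery and barcode
checks run on the default 1000×120 cohort with 50–100 surrogate
decompositions; ANOVA calibration uses 1000 null replicates and 20–25
power replicates at 150 samples (≈50 per critical point); the
Langevin–Boltzmann comparison in the acceptance script uses 10⁶ steps
(~600 barrier crossings) so the occupancy histogram's sampling error
does not mask engine agreement, while the seeded unit test demonstrates
the same agreement at 10⁵ steps. Stationary-state preservation is
checked on an 801-point grid (the exponential-fitting scheme's drift
scales with h²); the Ornstein–Uhlenbeck comparison reaches L¹ error
below 1e-3 at 601 points.

## Known limitations

- The significance count's 95%-within-2σ rule has ≈0.45 percentage
  points of headroom against pure Gaussian residuals; a noise-floor
  estimate biased low by more than ~3% inflates the count. On data whose
  "stable" transcripts are not at the technical noise floor, prefer
  passing a known σ.
- Amplitude recovery is exact only up to the affine shift absorbed by
  the steady-state component; comparisons with planted amplitudes use
  correlations, which are shift-invariant.
- The c2 matching condition assumes a barrier inside (c1, c3) at the
  chosen scale; extreme occupancy ratios pin c2 near a well and warn.
- The 1-D state-space keeps a single component; multi-dimensional
  state-spaces and nonlinear embeddings are out of scope.
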