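# Methods

This note records the statistical model behind the package, the defaults and
why they are what they are, and the places where the design was genuinely
open and a choice had to be made.

## The ROTS core

Both ROTS-based modules and the baseline rest on one engine
(`rolde.rots`). The statistic family is

* two groups: d = |x̄₁ − x̄₂| / (α₁ + α₂·s), s the pooled standard error of
  the mean difference;
* G ≥ 3 groups: d = √MSB / (α₁ + α₂·√MSW), MSB/MSW the between/within mean
  squares of a one-way ANOVA over the observed values.

At α = (0, 1) these reduce to the classical |t| and √F orderings, which the
tests verify (Spearman ρ = 1 against `scipy.stats`). A feature needs at
least two observed values in each of at least two groups to be scored;
groups a feature was never observed in drop out of its ANOVA terms; missing
values never raise, they only shrink counts.

The regularization is chosen by reproducibility optimization: for every α in
a grid (α₂ = 1 with α₁ ∈ {0, 0.01…0.1, 0.2…1, 1.5, 2, 3, 5}, plus the
fold-change-like (1, 0)) and every top-list size k in a geometric grid from
25 up to min(K, N/4), the mean proportional overlap R_k of the two top-k
lists over B bootstrap pairs (observations resampled within groups,
preserving group sizes) is compared with its null counterpart R0_k from
group-label-permuted bootstrap pairs; the (α, k) maximizing
Z_k = (R_k − R0_k)/sd(R0_k) wins. Ties in top-k lists break by stable
feature index. B defaults to 500; the benchmark and acceptance runs use
B = 100, which selects the same regularization on data of this size at a
fifth of the cost (the per-protein scores enter downstream only through
ranks, which are insensitive to the residual Monte-Carlo noise in Z).

Per-feature significance values are pooled permutation p-values: statistics
from n_perm group-label permutations are pooled over all valid features and
p = (1 + #{null ≥ observed})/(1 + #null). n_perm defaults to the smallest
count giving ≥ 10⁵ pooled comparisons. Whether the reference method
calibrates its run-level significance values this way is not documented
anywhere we could check; pooled permutation is the assumption made here, and
the null-calibration tests show it delivers run-level p-values that are
uniform to KS < 0.05 under the null, which is all the downstream simulation
requires.

All randomness flows from one `numpy` `SeedSequence`; bootstrap and
permutation streams are spawned independently, so results are bit-for-bit
reproducible given a seed.

## RegROTS

Per-individual fits use a discrete orthogonal polynomial basis built by the
classical three-term recursion p_{j+1}(t) = (t − a_j)p_j(t) − b_j p_{j−1}(t).
Aligned studies share one unit-norm basis on the union time grid; non-aligned
studies use per-individual bases with the final L2 normalization omitted so
coefficients stay comparable across different grids. The default degree is
d = max{1, min(⌊m/2⌋, 4)}, m the median timepoint count. An individual's fit
is valid iff it has ≥ d + 1 observed values (timepoints within an individual
are unique by design invariant); invalid fits carry NaN coefficients and
simply drop out downstream.

Cross-condition pairs are organized into runs by a cyclic Latin square: with
n individuals per condition, run r pairs uᵢ with v₍ᵢ₊ᵣ₎ mod n, giving n runs
covering all n² pairs exactly once. With unequal sizes n₁ ≠ n₂ there are
max(n₁, n₂) runs of min(n₁, n₂) pairs; all n₁n₂ distinct pairs are covered
exactly once and no individual repeats within a run on either side.

The per-run multigroup comparison groups the Δβ observations by degree and,
by default, appends an **anchor group** of zero pseudo-observations (one per
pair). The tested null is "all coefficient differences are zero"; a plain
equality-of-group-means ANOVA cannot reject when every degree shifts by the
same nonzero amount, and anchoring at zero makes the stated null the tested
one. `anchor=False` disables this for sensitivity analysis. Run ranks use
average ties; a protein's score is the geometric mean of its ranks over the
runs in which it was scored, and a protein valid in no run gets a missing
module score (handled by the combiner).

## DiffROTS

Aligned: identical run structure, with per-timepoint expression differences
Δy_tuv as observations, grouped by timepoint plus the same zero anchor. A
difference is missing whenever either measurement is, so missingness
propagates but never aborts.

Non-aligned: for each degree j = 0…d (d = max{2, min(m − 1, 5)}), the model
y = β₀ + β_j tʲ + δ₀ᵤ + ε with a random individual baseline is fitted per
protein by profiled maximum likelihood (time is standardized before powering
to keep degree-5 regressors numerically tame). The residuals entering the
two-group ROTS comparison are **marginal** (y − Xβ̂, excluding the predicted
random intercepts): conditional residuals would absorb a constant condition
offset into the individual baselines and blind the module to exactly the
signal its degree-0 model exists to catch. The score is the minimum p over
degrees; degenerate fits skip their degree, and a protein with no fittable
degree gets a missing score.

The random-intercept fitter profiles the variance ratio ρ = τ²/σ² (the
per-individual block inverse reduces to Sherman–Morrison sums, so each
evaluation is O(N)) and optimizes log ρ on [−12, 12]. Landing on the lower
boundary collapses to OLS; the upper boundary triggers a per-individual
centering (fixed-effects) fallback. `statsmodels` MixedLM reproduces the
estimates on test fixtures but is far too slow to run per protein × degree.

## PolyReg

One regression per protein over all samples:
y = β₀ + Σβ_j P_j(t) + γ₀c + Σγ_j c·P_j(t), condition coded c = ±½ so γ_j is
the between-condition difference in the j-th trend coefficient; orthogonal
time polynomials keep the γ estimates nearly uncorrelated (tested: pairwise
|r| < 0.2 on balanced designs). Aligned studies use fixed-effects least
squares, batched over identical missingness patterns; non-aligned studies
add the random intercept, with conservative residual
df = N − p − (#individuals − 1) for the coefficient t-tests (a
Satterthwaite-style df was considered and rejected as an unnecessary
dependency for this use). Rank-deficient per-protein designs drop
non-estimable columns via pivoted QR; their γ terms leave the minimum. The
score is the raw minimum over the γ p-values — deliberately uncorrected
within protein, since calibration is delegated to the combiner's simulation.

## The combiner and its significance simulation

Module scores become ascending average-tie ranks; missing scores get the
worst rank N (deterministic, and consistent with reading "multiple poor
ranks push a protein to the end of the list"). This substitution is why the
pipeline returns a score and rank for 100% of proteins under any missingness
pattern. S_RolDE is the cube root of the product of the three ranks.

The null distribution of S_RolDE is simulated. Per RegROTS/DiffROTS run:
draw as many U(0,1) values as that run has valid experimental p-values, sort
them, assign them to proteins in the experimental rank order (this retains
between-run dependence), then replace each with the rank of the *nearest*
experimental p-value, ties toward the smaller rank (slightly inflating
simulated products, hence conservative). Min-p modules (PolyReg, non-aligned
DiffROTS) draw uniforms per coefficient, order them by the experimental
ordering and take per-protein minima. Simulated module scores are ranked and
combined exactly like the experimental ones. One simulation round yields N
products; rounds repeat until the pool holds ≥ n_sim (default 500,000)
values, all vectorized per run. Estimated p = #{simulated ≤ observed}/n_sim,
floored at 1/n_sim; BH (default) or Bonferroni adjustment follows.

The nearest-rank mapping is what gives the scheme its discrimination: under
the null the smallest uniform order statistic (~1/N) maps to the top
experimental ranks, but when genuine signal drives the top experimental
p-values far below 1/N, no simulated value lands near them and simulated
products rarely reach the observed extremes. A consequence worth knowing:
the estimated p-values are calibrated (uniform under the null, KS ≈ 0.01 in
the tests) but conservative in small studies with strong signal — with ~10⁵
pooled permutation comparisons the experimental p floor limits how far the
observed products can escape the simulated ones. Rankings, which the
benchmark metrics score, are unaffected.

## The synthetic benchmark generator

The generator reproduces the *structure* of spike-in benchmarks — a stable
but noisy background plus spike-ins following trend categories built from a
ladder of L concentration levels — with parametric draws in place of
resampled real spike-in groups (the real archives' per-protein means and
variances are not shipped). Values are drawn independently from
N(μ_ij, σ²_ij) per protein × (condition, timepoint) group. Defaults, chosen
once as typical of label-free data: baselines N(25, 2²) log2 units; group
standard deviations log-normal with median 0.3 log2 units (σ_log = 0.4);
adjacent ladder levels 1.0 log2 unit apart (mimicking a 2–4–10–25–50 fmol
series); L = 5; T = 5; 3 individuals per condition; 1000 background + 50
spike-in proteins.

The six categories are canonical shape functions on [0, 1] quantized to the
ladder: Stable (constant mid-level), Linear (monotone ramp across all
levels), LogLike (concave ramp), Sigmoid (plateau–steep–plateau), Poly2
(symmetric valley/peak), PolyHigher (≥ 2 interior direction changes). The
exact level sequences of the real benchmarks' non-linear categories are not
published in reusable form; these are shape-faithful synthetic stand-ins,
fixed as constants. Designs with T = 3, 4 truncate the canonical 5-point
sequences from the front. Spike-in directions alternate deterministically.

MNAR missingness is left-censoring: dropout probability is a logistic
function of intensity (scale 0.5 log2 units) with the threshold calibrated
by bisection so the expected overall rate hits the target; spike-ins can
carry their own rate (the benchmarks this emulates had ~19.5% overall and
~29.4% spike-in missingness). MCAR is uniform.

What passing these benchmarks does *not* show: the generator has no
peptide-level structure, no correlated noise across proteins, no
normalization artifacts and Gaussian (not heavy-tailed) replicate noise, so
real-data performance claims still require real data.

## Problem sizes and numerical choices

The test suite and acceptance script run the pipeline at 300–1050 proteins,
3v3 individuals, T = 5, with B = 100 bootstrap pairs, n_perm ≈ 100 (10⁵
pooled comparisons) and n_sim = 10⁵ simulated rank products — sizes at which
every stochastic check (null KS, pAUC bounds, recovery rates) is stable
across seeds while a full pipeline run takes seconds. Tolerances: exact
oracle equivalences at 1e−12 (rank products, pAUC sweeps), basis
orthogonality at 1e−10, stochastic bounds with explicit Monte-Carlo margins
(e.g. FDP ≤ 0.10 at nominal 0.05). Tie-breaks are deterministic everywhere
(stable index in top-k lists, smaller rank in the nearest-p mapping, average
ranks in scores).

## Known limitations

* Exactly two conditions; no random slopes in the mixed models; no
  time-interval localization of effects.
* Estimated significance is conservative under strong signal in small
  cohorts (see above); interpret BH-adjusted p-values accordingly and use
  ranks for benchmarking.
* The evaluator's standardized pAUC uses the McClish rescaling on the
  specificity band [0.9, 1]; an anti-perfect classifier therefore maps to
  ≈ 0.447, not 0 — raw areas are available via `standardized=False`.
* The generator's defaults describe one realistic operating point, not the
  full diversity of instrument platforms.
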