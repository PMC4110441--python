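# Methods

## Model

Observations are continuous indicator vectors `y` of length p for Level-1
units (students) nested in Level-2 clusters (classes) nested in Level-3
clusters (schools). The random-effects measurement model is

    y_ics = μ + u_s + v_cs + e_ics,
    cov(u) = Σ_L3,  cov(v) = Σ_L2,  cov(e) = Σ_L1,

with all components independent multivariate normal, so the total
covariance decomposes as Σ_total = Σ_L3 + Σ_L2 + Σ_L1. Each level carries a
linear factor structure Σ_Lm = Λ_m Φ_m Λ_mᵀ + Θ_m with diagonal Θ_m.
Two-level data are the special case without the `u` term; a single-level
spec (plain multivariate normal) is also accepted so that reference models
degrade gracefully.

Strong factorial invariance across clusters at a level is expressed as
loadings equal across levels (one shared parameter label per indicator)
together with Θ = 0 at that level. The cluster-bias test therefore compares
three nested models: the baseline with Λ tied across levels and all Θ_m
free; the same model with all p Level-2 residual variances fixed at 0; and
the same model with all p Level-3 residual variances fixed at 0 (Level-2
residuals free again — each constrained model is compared against the
baseline). Residual variance at an aggregated level is interpretable as
structural (bias) variance because random measurement error averages out
within clusters; only at Level 1 is specific variance confounded with
random error. The test cannot distinguish violations of weak from strong
invariance: cluster-varying loadings also surface as higher-level residual
variance, and the simulator can generate exactly that scenario
(`loading_sd_level2`) to demonstrate it.

### Identification

The common-factor scale is set by fixing its variance to 1 at Level 1 and
estimating all p loadings; the factor variances at Levels 2 and 3 are free,
which is what makes the factor intraclass correlations directly readable
from the estimates. The alternative (first loading fixed at 1, all factor
variances free) is available via `fix_first_loading=True` and yields the
same degrees of freedom. The mean structure is always saturated: p free
intercepts, never constrained, housed in the mean vector.

Specific covariance between an indicator pair (a "doublet") is modelled as
an extra orthogonal factor with both loadings fixed at 1 and a free
variance at every level — equivalent to a residual covariance at Level 1
but, unlike one, well-defined at the higher levels where Θ must stay
diagonal for the invariance constraint to make sense. In the constrained
models the doublet variances remain free; only the p residual variances
are fixed, so each constraint step removes exactly p parameters and the
difference test has p degrees of freedom.

### Degrees of freedom

Sample moments are counted as p means plus one p(p+1)/2 covariance matrix
per level; df = moments − distinct free labels. For p = 8 with one doublet
this gives 45 free parameters and df 71 for the baseline, 79 for either
constrained model.

## Likelihood evaluation

The exact joint log-density is evaluated from lossless sufficient
statistics. Each class is orthogonally split into its mean and n_c − 1
within-class contrasts; the contrasts contribute

    −½ [ (N − C) log|Σ_L1| + tr(Σ_L1⁻¹ S_W) ]

with S_W the pooled within-class scatter, plus the Jacobian term
−(p/2) Σ_c log n_c from expressing the mean coordinate as ȳ_c rather than
√n_c ȳ_c. Within a school, the class means have covariance
blockdiag(V_c) + 1 1ᵀ ⊗ Σ_L3 with V_c = Σ_L2 + Σ_L1/n_c. That block is
handled by the Woodbury identity in the form

    Ω⁻¹ = D⁻¹ − D⁻¹ U Σ_L3 (I + A Σ_L3)⁻¹ Uᵀ D⁻¹,   A = Σ_c V_c⁻¹,
    log|Ω| = Σ_c log|V_c| + log|I + A Σ_L3|,

which never inverts Σ_L3 — essential because the constrained models and
boundary solutions make Σ_L3 exactly singular (rank ≤ number of factors) and
the likelihood must remain exact there. V_c inverses are cached per unique
class size, so balanced designs cost one p×p factorization per level.
Exactness is enforced by tests comparing against a brute-force stacked
(Σ n_c)p × (Σ n_c)p normal density on random unbalanced instances
(tolerance 1e-8; in practice agreement is ~1e-13).

Inadmissible points (Σ_L1 or some V_c not positive definite, or
|I + A Σ_L3| ≤ 0) return −∞, which the optimizer sees as a large finite
penalty barrier.

## Estimation

- **Optimizer**: L-BFGS-B with lower bound 0 on every variance-type
  parameter (factor-covariance diagonals and residual variances); other
  parameters unbounded. Finite-difference gradients.
- **Starting values**: moment decomposition — S_W/(N−C) for Σ_L1; the
  covariance of class/school means, corrected for lower-level leakage and
  floored at a small positive value, for the higher levels. Loadings start
  at half the within variance; saturated/independence specs start at the
  moment estimate of each covariance cell. Explicit starts can be given
  per entry in the spec or per fit.
- **Convergence**: relative objective change below 1e-11 and projected
  gradient below 1e-5, max 500 iterations. On failure, up to three
  restarts with seeded multiplicative jitter (25%) around the starts; the
  best attempt is kept and `converged=False` is reported honestly —
  nonconvergence of a saturated Level-3 model on data with few schools is
  an expected outcome, not an error.
- **Standard errors**: inverse observed information from central second
  differences at the optimum. Parameters within tolerance of their lower
  bound are flagged `at_boundary` and get no SE (the information matrix is
  not the right curvature object on the boundary); Wald tests skip them.
- **Reference models**: saturated and independence models run through the
  same engine as structured models, as identity-loading specs with free
  (full or diagonal) factor covariances, so all df bookkeeping is uniform.

## Fit indices and tests

- χ² = 2(ℓ_saturated − ℓ_model), clipped at 0.
- RMSEA = √(max(χ² − df, 0)/(df·N)) with N the total number of Level-1
  units (this convention reproduces standard published multilevel fit
  tables; configurable in principle via direct calls).
- CFI uses the independence model (diagonal Σ at every level, free means)
  as its baseline and is clipped to [0, 1].
- Δχ² tests use the central χ² distribution with Δdf = the parameter-count
  difference. Fixing variances at zero places the true parameter on the
  boundary of the parameter space, where the LR statistic is a mixture of
  χ² distributions; the central reference therefore yields a conservative
  test. The package states this caveat in every report rather than
  implementing chi-bar-square mixtures, and ships a type-I-error study
  harness that demonstrates the conservativeness empirically.
- Reports print proportions/ICCs to 3 decimals and fit indices to 2.

In the assembled `ClusterBiasReport`, Wald tests, bias proportions and
factor ICCs are read off the baseline fit, where both Level-2 and Level-3
residual variances exist as free parameters.

## Synthetic data

`simulate_dataset` draws from exactly the generative model above: common
factor at all levels (variances φ₁, φ₂, φ₃), per-level residual vectors,
optional doublet factors, optional per-class loading perturbation. Cluster
sizes may be constant, per-cluster lists, or draws from a discrete
distribution (to mimic unbalanced field data). What it deliberately does
not emulate: non-normal indicators, categorical/ordinal scoring, missing
data mechanisms, and non-nested (crossed) clustering. Passing tests on
these data therefore certify the estimator and test mechanics under the
model's own assumptions, not robustness to their violation.

Monte-Carlo studies spawn one `SeedSequence` substream per replicate from a
master seed, making rates reproducible bit-for-bit and replicates
order-independent. Studies with more than 20% nonconvergence are flagged
unreliable. The study drivers fit only the baseline and the tested level's
constrained model per replicate (the Δχ² statistic needs nothing else).

## Default study conditions and problem sizes

- Null (type-I) study: p = 4, loadings 0.7, φ = (1, 0.3, 0.1), Level-1
  residuals 0.5, zero Level-2/Level-3 residuals; 50 schools × 3 classes ×
  10 students; M = 200 replicates. At these sizes the Level-3 rejection
  rate at nominal α = 0.05 is far below nominal (often 0/200), the boundary
  conservativeness in action.
- Recovery check: 200 schools × 4 classes × 25 students, p = 4; loading
  estimates land within 0.005 of truth, comfortably inside the 0.05
  acceptance band.
- Oracle equivalence: 100 random instances of 1–3 schools, 1–3 classes,
  1–4 students, p ≤ 4, including rank-deficient and zero Σ_L3.

These sizes were chosen as the smallest designs at which the respective
properties are cleanly visible; all are fixed-seed and deterministic.

## Known limitations

- Complete-case handling of missing indicator values; row-wise FIML for
  item missingness is out of scope (the "full information" here refers to
  the multilevel structure and unbalanced cluster sizes).
- No sandwich/robust standard errors, no categorical indicators, no more
  than three levels, no crossed random factors, no modification indices.
- Full factor covariance matrices (saturated specs) are not constrained to
  be positive semidefinite during optimization; inadmissible iterates are
  handled by the likelihood barrier, and near-singular higher-level
  solutions can legitimately fail to converge.
- The χ²-difference p-values are conservative by construction at boundary
  nulls; power statements at small cluster counts should be read
  accordingly.
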