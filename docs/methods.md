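# Methods

## The model

`kldm` infers condition-specific microbial association networks from
marker-gene count tables. It assumes the data were collected under `K`
latent *environmental-factor (EF) conditions*. Per sample `i` under
condition `c`:

    c_i  ~ Categorical(pi)
    m_i | c_i  ~ N(mu_c, Sigma_c)                       (EF values)
    z_i | c_i  ~ N(B0_c, Theta_c^{-1})                  (latent deviations)
    alpha_i    = exp(B_c^T m_i + z_i)                   (absolute abundance)
    h_i        ~ Dirichlet(alpha_i)                     (latent composition)
    x_i        ~ Multinomial(depth_i, h_i)              (read counts)

Two matrices carry the biology: `B_c` (Q x P) holds direct EF-OTU
effects on log abundance, and the sparse precision `Theta_c` (P x P)
holds conditionally dependent OTU-OTU associations, reported as partial
correlations `-Theta_ij / sqrt(Theta_ii Theta_jj)`. The
Dirichlet-multinomial layer absorbs the compositional bias of sequencing
(normalizing counts by the sample total induces
`sum_{k!=j} Cov(r_k, r_j) = -Var(r_j)`, an artificial negative
dependence) and the heavy overdispersion of read counts, so neither is
mistaken for ecology.

## Single-condition inference

`fit_single_condition` alternates three blocks:

1. **Latent MAP.** All samples' `z_i` are maximized jointly (the
   objective is separable, so one L-BFGS-B run over the stacked
   variables) for the Dirichlet-multinomial term plus the Gaussian
   prior, with analytic gradients via digamma functions.
2. **EF effects.** `B` by l1-penalized least squares of the total
   latent log abundances on centered EF values (coordinate descent;
   closed-form ridge-stabilized OLS at lambda = 0); `B0` is the
   unpenalized intercept.
3. **Precision.** `Theta` by graphical lasso on the covariance of the
   latent residuals, with a relative 1e-3 variance floor on the diagonal
   so a residual column collapsing onto its prior mode cannot send the
   precision to infinity.

Penalties are chosen on data-driven log-spaced grids (5 values per
penalty spanning two decades below the null-model threshold) by the
extended BIC. The scan is sequential and warm-started: the `lambda_B`
grid is searched first with the precision held diagonal, then the
`lambda_Theta` grid at the selected `lambda_B`, and the winning pair is
polished with extra outer iterations. The B-before-Theta order matters:
scanned the other way, the free precision matrix absorbs EF-driven
variation as spurious covariance and the information criterion then sees
no value in any EF coefficient. Outer iterations are capped at 8 during
the scan and 15 in the polish; the relative-change tolerance of 1e-4
usually triggers earlier, but the joint objective has a nearly flat
overall-scale direction (the total abundance `sum alpha` is only weakly
identified by the counts) that would otherwise consume any iteration
budget for negligible parameter movement.

### Information criterion

`ebic_score` is the Foygel-Drton form with both edge spaces charged:

    EBIC = -2 loglik + (df_T + df_B + df_free) log n
           + 4 gamma df_T log P + 2 gamma df_B log(QP),     gamma = 0.5

with two refinements that matter when EBICs of *different sample
partitions* are compared (the merge decisions below):

- `loglik` is a **Laplace approximation of the marginal likelihood** of
  the counts: the latent `z_i` are integrated out using the per-sample
  Hessian (prior precision plus the floored curvature of the count
  term) rather than plugged in at the MAP. Plugin scores silently
  reward whichever model can sharpen its precision against its own
  residuals, which biases cluster comparisons.
- `df_free` charges the unpenalized parameters every fit estimates
  (`B0`, the precision diagonal, and the EF moments) at `log n`.
  Without it, splitting a cluster duplicates those parameters for free.

### Association scores versus selected support

The EBIC-selected support is deliberately conservative: at realistic
sample sizes an individually weak but real edge cannot justify its own
`~log n` charge, yet a ROC analysis only needs the edges *ranked*
correctly. Each fitted condition therefore carries two objects:

- the sparse selected model (`B`, `Theta`) — defines `df`, the reported
  edge lists, merge decisions, and the near-empty behavior on null data;
- continuous ranking scores: `B_score`, the standardized OLS
  coefficients (|t|) of the latent log abundances on the EFs (per-OTU
  residual noise varies strongly with abundance, so |t| outranks |b|),
  and `Theta_score`, the graphical-lasso regularization-path entry
  order (an edge entering at a stronger penalty carries more evidence).

Evaluation uses the scores when present and falls back to |coefficient|
and |partial correlation| otherwise.

## Split-merge estimation of K

- **Split.** Recursive bisection of samples in EF space with
  2-component Gaussian mixtures (EM on per-factor z-scores, k-means
  initialization, 3 restarts, best by likelihood). A split is rejected
  if it would create a child below `n_min = max(Q + 2, 30)` samples.
- **Leaf fits.** Each leaf gets a single-condition fit; leaves smaller
  than P first shed their lowest-total OTUs (`otu_filter`) so the
  network never has more nodes than samples.
- **Merge.** Internal nodes deepest-first; at each node the closest
  pair of clusters across the two branches (Euclidean distance of
  z-scored EF means) is test-merged and kept iff
  `EBIC(merged) < EBIC(a) + EBIC(b)`. Because small clusters may keep
  different OTU subsets, all three fits entering a comparison are
  restricted to the intersection of the pair's kept OTUs; an accepted
  merge is refit on its own natural filter and takes the tree slot of
  the member whose EF mean is closer to the merged mean.
- **Sweep and reassignment.** After the tree pass, a closest-pair merge
  sweep runs among the surviving clusters (pairs that ended under
  different branches of an early split can otherwise never meet), and
  samples are reassigned to the condition maximizing
  `log pi_k + log N(m_i; mu_k, Sigma_k) + marginal count loglik`,
  followed by refits; the sweep/reassignment pair is iterated at most
  twice. The reassignment uses the model's own posterior — both the EF
  values and the association networks decide the condition — and
  repairs the EF-boundary contamination a purely EF-based split leaves
  behind. Clusters falling below `n_min` are dissolved.

Everything is deterministic given (data, config, seed); node seeds are
derived from the config seed and the node id.

## Synthetic data generator

Defaults follow the study conditions the model targets: `B` has exactly
`round(0.15 Q P)` nonzero entries uniform on `[-0.5, 0.5]` excluding a
+-0.05 dead zone (a "true" edge of size 1e-3 would make ROC ground truth
meaningless); precision support is one of five graph families (random
Erdos-Renyi with edge probability 3/P, dense-block cluster, preferential
attachment scale-free, star-union hub, band), off-diagonal magnitudes
uniform 0.2-0.5 with random sign, diagonal lifted so the smallest
eigenvalue is 0.1 and then rescaled so implied marginal variances are
exactly 1 (the convention of standard sparse-precision simulators);
condition-k EF means are uniform on `[k, 1.5k]` per coordinate, or
placed exactly `d` apart when a separation override is given; EF
covariance defaults to `0.25 I` (with-in condition spread sd 0.5, which
makes separation 1.0 borderline for mixture splitting and 1.5-2.0
comfortable — matching how separation is meant to behave); the basis
`B0 = ln(alpha0 * p)` with `p ~ Dirichlet(2)` and `alpha0 = P`, giving
mean concentration ~1 per OTU, i.e. the strong overdispersion typical
of fitted 16S data; sequencing depth uniform in [5000, 50000].

What the generator does **not** emulate: rare/absent OTUs (all taxa are
present in all conditions), non-Gaussian or categorical EFs, depth
confounded with condition, and taxonomic structure. Passing tests show
the estimator recovers the model's own data; they do not certify
behavior under real-data violations of these assumptions.

A note on attainable accuracy: with EF spread sd 0.5, coefficients
bounded by 0.5 and per-OTU latent noise of order 1 (biological variance
plus Dirichlet overdispersion), even an oracle given the true latent
abundances recovers EF-OTU edges with AUC only ~0.8 at N = 400, P = 20.
Recovery figures should be read against that ceiling, not against 1.0.

## Problem sizes used in tests and the acceptance script

The acceptance script runs the full pipeline on the two-condition
design (P = 50, Q = 5, N per cluster in [100, 200], separation 1.5) for
three consecutive seeds and reports the median of the per-seed minimum
AUCs, plus the mean inverse Simpson index of the two large generator
settings (P = 100 and P = 200). The test suite uses the same designs
where a claim prescribes them and smaller ones (P = 10-30, N = 100-400)
for structural checks, which keeps the default suite within ordinary
laptop runtimes.

## Known limitations

- MAP latent estimation understates latent uncertainty; the Laplace
  correction enters the information criterion but not the parameter
  estimates themselves.
- The EBIC merge rule compares greedy closest pairs only; a full search
  over cluster pairings is exponential and not attempted.
- Categorical EFs must be recoded to ordinal integers by the user; the
  Gaussian mixture treats them as continuous.
- No posterior uncertainty (credible intervals) on associations.
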