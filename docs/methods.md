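# Methods

`rhizonet` analyses dose-gradient amplicon surveys of rhizosphere
microbial communities: a control plus several inoculant doses, a few
replicates each, with 16S/ITS ASV count tables, taxonomy, soil
physicochemical covariates and (optionally) a rooted phylogeny as
inputs. This note records the statistical definitions, conventions and
design choices the code implements, the assumptions behind the
synthetic-data generator, and the package's known limitations.

## Alpha diversity

All estimators act on one sample's non-negative integer count vector;
zero-count taxa are ignored. With S_obs observed taxa, N total reads,
F1/F2 singleton and doubleton counts:

- Shannon H = −Σ p_i ln p_i, in **nats** (a community of ~1,900 evenly
  spread taxa gives H ≈ 0.91·ln 1907 ≈ 6.9, the scale practitioners in
  this field report).
- Pielou J = H / ln S_obs. For S_obs = 1 the ratio is 0/0; the limit
  convention J = 1 is returned.
- Simpson is the **unbiased dominance** estimator
  D = Σ n_i(n_i−1) / (N(N−1)) — small values mean high diversity; this
  is the dominance scale (values ~0.002 for rich bacterial
  communities), not 1−D.
- Good's coverage = 1 − F1/N.
- Chao1 is the **bias-corrected** form S_obs + F1(F1−1)/(2(F2+1)), the
  mothur convention: the +1 in the denominator avoids division by zero
  when no doubletons exist, at the price of Chao1 = S_obs whenever
  F1 ≤ 1.
- ACE uses the conventional rare/abundant cutoff of 10. When the rare
  group's sample coverage C_ACE is zero (every rare taxon a singleton)
  ACE is undefined; the code warns and falls back to Chao1.

Rarefaction is a single seeded multivariate-hypergeometric draw per
sample (sampling without replacement), not an average over repeated
draws — this matches fixed-depth normalisation as usually practised.
Whether indices are computed before or after rarefaction is the
caller's choice (`alpha_table(depth=None)` disables it); the default
pipeline rarefies first. The bacterial and fungal depths used by the
pipeline's `marker` presets are 38,278 and 22,075 reads per sample;
`depth="auto"` uses the minimum sample total instead so that arbitrary
tables never fail the depth precondition.

## Beta diversity and ordination

- **Abundance-weighted Jaccard** is implemented as the Ružička index
  1 − Σ min(x_i, y_i) / Σ max(x_i, y_i). The Chao–Chazdon probabilistic
  abundance-based Jaccard estimator is available via
  `variant="chao"`; the name "abund-jaccard" does not pin down one
  estimator, and Ružička is the direct quantitative generalisation.
- **Unweighted UniFrac** between two presence sets: numerator = branch
  length covered by exactly one sample (a branch is covered when any
  descendant tip is present); denominator = the **total branch length
  below the lowest common ancestor of all present taxa**, including
  branches leading only to taxa absent from both samples. Branches
  above that LCA are excluded. This total-length denominator is the
  original Lozupone-style convention; QIIME/scikit-bio instead restrict
  the denominator to covered branches, so values agree between the two
  conventions exactly when the union of the two samples spans every
  leaf under the LCA (the test suite cross-checks against scikit-bio in
  that regime). Taxa missing from the tree raise in strict mode or are
  pruned with a warning in lenient mode.
- **PCoA** eigendecomposes the Gower-centered matrix −½ J D² J.
  Negative eigenvalues are retained and reported without Cailliez or
  Lingoes correction; coordinates are returned for positive-eigenvalue
  axes only, and proportion explained is computed over the positive
  part of the spectrum.
- **PERMANOVA** uses the pseudo-F on partitioned squared distances,
  SS_T = Σ_{i<j} d²_ij / N and SS_W = Σ_g Σ_{i<j∈g} d²_ij / n_g;
  **ANOSIM** uses R = (r̄_between − r̄_within)/(M/2) on tied-rank
  distances. Both permute group labels over samples and report the
  add-one p-value (1 + #{stat_perm ≥ stat_obs})/(1 + n_perm), so p is
  never 0 and never below 1/(n_perm+1). An exhaustive mode enumerates
  all label orders for N ≤ 9 and reports the exact permutation
  fraction.

## Co-occurrence networks

The network pipeline is: aggregate ASVs to genus through the taxonomy
map (identifiers are never parsed), keep the top-N genera by mean
relative abundance (ties broken lexicographically), correlate
per-sample **relative abundances** with Spearman's ρ (Pearson on
mid-ranks; two-sided p from the t approximation with n−2 df), adjust
the upper-triangle p-values with Benjamini–Hochberg, and keep edges
with |ρ| ≥ 0.6 (inclusive; a flag switches to strict) **and** adjusted
p < 0.05. Conventions:

- Correlating relative abundances rather than counts only matters when
  sample depths differ (Spearman is rank-based); closure is applied for
  definiteness.
- Using the FDR-adjusted p against the 0.05 threshold is the stricter
  of the two readings of "p < 0.05 with BH correction"; raw-p mode is a
  flag. Each network (e.g. bacterial vs fungal) is its own BH family.
- Zero-variance taxa have undefined ρ; they are dropped from the
  network by default (`keep_constant=True` retains them as isolated
  nodes). Isolated nodes that merely fail the edge thresholds are
  always retained.
- |ρ| = 1 makes the t statistic infinite; p is reported as 0 with this
  caveat: at small n a perfect rank agreement is not actually
  impossible under the null, so such edges should be read as "monotone
  in every sample", not as infinitely significant.
- Genus labels unassigned at genus level pool under
  `unclassified_<deepest resolved coarser rank>`.

Topology summaries report density 2E/(N(N−1)) and the positive-edge
fraction (0 for an edgeless graph).

Per-treatment networks run the same pipeline independently per group.
Spearman p-values over n < 4 samples are meaningless (with n = 3, ρ can
only take a handful of values), so groups below `min_samples = 4`
raise. A 3-replicate design therefore supports pooled networks but not
honest per-treatment ones; how the original per-treatment analyses were
computed from 3 replicates is underdetermined, and the package refuses
to guess silently — callers must either pool or lower `min_samples`
explicitly.

## Null-model connector detection

A connector taxon bridges modules: few links, many shortest paths. The
null model is Maslov–Sneppen degree-preserving rewiring: repeated
double-edge swaps (a,b),(c,d) → (a,d),(c,b), accepted only when no
self-loop or parallel edge would result, until `swaps_per_edge × E`
swaps succeed (default 10 swaps per edge, a standard mixing budget; the
randomisation count, 1,000, is separate). An attempt cap of 100× the
budget guarantees termination on rigid graphs — a triangle, whose
degree sequence admits exactly one simple graph, returns unchanged.
Node labels ride through the swaps (edges move, labels do not), so each
node's null betweenness distribution is well defined.

Betweenness is raw (unnormalised) shortest-path betweenness with
unordered pairs counted once and fractional credit across equal-length
paths, computed identically on observed and null graphs (only
comparisons matter). Signs/weights are ignored; the null model operates
on the topology alone, and only total degree (not signed degree) is
preserved. Disconnected graphs are allowed — cross-component pairs
contribute no paths.

A node is a connector when all three hold (strict inequalities,
percentiles by linear interpolation):

1. observed betweenness > 95th percentile of its own null sample
   (equivalently empirical p = (1 + #{B_null ≥ B_obs})/(1 + n_random)
   ≲ 0.05, up to the discreteness of the null sample);
2. observed betweenness > 75th percentile of all observed betweenness;
3. degree < 25th percentile of all observed degrees.

## Taxa–environment network

Spearman between the top-50 genera's relative abundances and each
covariate, with one joint BH family over all genus × covariate pairs
(a single family is the conservative, simple choice). Significance is
|ρ| > 0.6 strictly and adjusted p < 0.05; the threshold is read as a
magnitude, since strong negative correlations are as meaningful as
positive ones. A coverage check reports the fraction of reads the
top-N genera capture and warns at ≤ 50%. Note that perfect reported
correlations (ρ = ±1) at n ≤ 15 typically indicate correlation on
treatment means or heavy ties; this package always correlates at the
sample level.

## Differential abundance

Per-taxon Kruskal–Wallis on relative abundances with the standard tie
correction; all-identical values give H = 0, p = 1 by convention
(rather than an error). BH is applied **across taxa** for the omnibus
p, and Dunn's z tests (tie-corrected pooled-rank variance) run only for
taxa whose corrected omnibus p clears the threshold, with BH applied
**within each taxon's pairwise family**. Other family layouts are
defensible; this one matches reporting per-genus p and p_adj.

## Venn partition

An ASV is present in a group when its counts summed over the group's
replicates reach `min_count` (default 1 — any replicate suffices;
exposed as a flag since all-replicate presence is an equally defensible
rule). Every ASV maps to exactly one region (its exact presence
pattern); core, group-unique and "shared exclusively among S" are
region lookups.

## Synthetic data generator

`synthesize` draws studies with planted, returnable ground truth:

- **Design**: default 5 groups (CK, T1–T4) × 3 replicates, matching a
  dose-gradient field trial; mean sequencing depth 42,409 reads per
  sample (a realistic post-filtering average for soil amplicon runs).
- **Correlation structure**: a Gaussian copula. The latent Pearson
  correlation is set to 2 sin(πρ_s/6) so the copula's population
  Spearman equals the target ρ_s exactly; negative-binomial marginal
  quantile transforms (dispersion r = 10, a moderately overdispersed
  soil-like setting) preserve the ranks up to count discreteness.
  Targets are module blocks (constant within-block ρ) plus optional
  connector taxa.
- **Connectors and correlation geometry**: a taxon correlated ≥ 0.6
  with single members of two mutually independent tight modules makes
  the correlation matrix non-positive-semi-definite — correlation
  transitivity forbids exactly-degree-2 bridges at that threshold. The
  generator therefore couples each connector to **both modules' common
  factors** (every member, at `connector_rho = 0.65`, within the PSD
  bound √(ρ_module/2)); the result bridges the modules but is not
  degree-2. Exact degree-2/high-betweenness ground truth for the
  detector instead comes from `planted_connector_graph`, which builds
  complete-graph modules chained by degree-2 bridge nodes and verifies
  at construction that every bridge provably satisfies the percentile
  criteria.
- **Group effects** are positive multiplicative fold-changes applied to
  baseline (lognormal, σ = 1.2) abundances before per-sample closure,
  so enrichment of one taxon implicitly dilutes the rest — the
  compositional behaviour real relative abundances show. The default
  study's dose response peaks at the middle dose (5× enrichment in T2)
  with matching suppression (0.2×) of a "pathogen-like" block.
- **Environment covariates** are monotone functions of designated
  taxa's **latent** values (not counts) plus Gaussian noise
  (σ = 0.3), keeping couplings monotone under depth variation. They
  are reported standardised; units are arbitrary.
- **Reproducibility**: one root seed, `Generator.spawn` substreams in a
  fixed order (baselines, latent field, environment).

What the generator does **not** emulate: read-level error and chimera
processes, taxon-specific amplification bias, the extreme sparsity and
long tail of real ASV tables (default 60 taxa, all fairly abundant),
phylogenetic signal in the correlation structure, and spatial/temporal
autocorrelation between plots. Passing recovery tests therefore shows
the estimators and thresholds behave correctly when their assumptions
hold — not that a 3-replicate field study has power to detect these
structures in real data.

## Numerical choices and problem sizes

- BH, Spearman, the permutation statistics and the rank tests are exact
  reimplementations validated against brute-force oracles (and scipy /
  statsmodels / scikit-bio cross-checks) to 1e−10…1e−12.
- Percentiles use numpy's linear interpolation between order
  statistics throughout.
- Betweenness is computed through igraph's C implementation (the null
  model needs thousands of evaluations per network); the test suite
  verifies exact agreement with exhaustive path enumeration and with
  networkx's Brandes algorithm.
- Validation experiment sizes were chosen once as the smallest designs
  that make the stochastic recovery criteria statistically stable:
  planted-edge recovery uses 2 modules of 6 taxa among 100 taxa at
  n = 100 samples over 5 seeds; connector recovery uses 3 modules of 8
  nodes with 1,000 randomisations over 50 seeds (25 in the acceptance
  script); calibration uses 2,000 null replicates at n = 15 in the
  test suite and 1,000 in the acceptance script.
- In the planted-edge recovery experiment the modules deliberately hold
  a small compositional share (12 of 100 taxa). When tightly correlated
  modules dominate a community, per-sample closure induces genuine
  negative Spearman correlation between them — a property of relative
  abundances, not a false positive of the statistics — which would be
  indistinguishable from spurious edges in a ground-truth comparison.
  Real top genera hold small shares, so the small-share design is both
  the realistic case and the one that isolates the correlation/FDR
  machinery the experiment is meant to validate.

## Known limitations

- Spearman networks are not compositionality-aware (no SparCC /
  SPIEC-EASI); at 60–100 well-mixed taxa closure-induced correlation is
  modest, but for few dominant taxa it is not.
- Per-treatment networks from 3 replicates are statistically
  underdetermined; the package makes this explicit rather than
  reproducing such numbers.
- p = 0 for |ρ| = 1 edges (see above) slightly overstates evidence at
  very small n.
- The chi-square approximation to Kruskal–Wallis is conservative at
  3 observations per group: on null simulations at 5 groups × 3 the
  empirical type-I error at nominal 0.05 is ≈ 0.015–0.02 (scipy's
  implementation behaves identically), approaching the nominal level
  only for ~10 or more observations per group. At the 3-replicate
  design, KW discoveries are therefore trustworthy but its power is
  lower than the nominal level suggests.
- The exhaustive PERMANOVA mode enumerates all N! label orders and is
  limited to N ≤ 9.
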