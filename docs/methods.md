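# Methods

This note documents the statistical models and procedures `enterokit`
implements, the defaults it ships, and the choices made where the
literature leaves the design open.

## The analysis the package reproduces

Large 16S rRNA cohort studies of the healthy adult gut follow a fairly
standard arc once reads have been denoised to a genus- or ASV-level count
table: rarefy to a common depth, discard rare features, describe each
sample's richness and evenness (alpha diversity), compare community
composition between groups of samples (beta diversity with permutation
tests), cluster samples into recurring community types — *enterotypes* —
and test individual taxa against host phenotypes with false-discovery-rate
control. `enterokit` packages that arc as composable scikit-learn-style
estimators plus a config-driven pipeline, and pairs it with a synthetic
cohort generator so every stage can be validated against known ground
truth.

## Preprocessing

**Rarefaction** subsamples each sample's counts *without replacement*
(multivariate hypergeometric) to a fixed depth, default 2000 reads.
Samples below the target depth cannot be rarefied and are dropped with a
report rather than an error — in practice a handful of shallow libraries
should not abort a cohort analysis. Without-replacement sampling gives the
two properties the tests assert: a taxon absent before rarefaction stays
absent, and the expected post-rarefaction count equals depth × the
within-sample relative abundance.

**Rare-feature removal** drops a taxon when *any* of three rules fires:
total count < 5, observed in at most one sample, or overall relative
abundance below 0.1%. "Overall relative abundance" is read table-wide
(taxon total over grand total), the common QIIME 2 interpretation; a
per-sample maximum-abundance alternative is available via
`per_sample_abundance=True` since the convention varies between
ecosystems. Thresholds are exclusive below: exactly 0.1% is not "below
0.1%". The filter is idempotent — removing taxa only raises the surviving
taxa's overall shares, so a second pass removes nothing.

**Detection-rate classes.** A taxon's detection rate is the fraction of
samples in which it has a nonzero count. Low-frequency flora are those
with rate < 10%, high-frequency > 70%, medium-frequency everything in
between. Rates of exactly 10% or 70% are classed medium: with strict
inequalities on both outer classes, the closed middle interval is the only
reading that covers all rates.

## Alpha diversity

Chao1 is computed in the bias-corrected form
S_obs + F1(F1−1)/(2(F2+1)), which is defined even with no doubletons and
matches scikit-bio and the QIIME 2 default. Shannon entropy is reported in
bits (log base 2, the QIIME 2 convention); the base is an argument. Group
comparisons use the Kruskal–Wallis test with tie correction and the χ²
asymptotic p-value on k−1 degrees of freedom.

## Beta diversity

Five pairwise dissimilarities are provided:

* **Root-JSD** — the enterotyping metric. For profiles p_a, p_b,
  D(a,b) = sqrt(½ KLD(p_a, m) + ½ KLD(p_b, m)) with m the midpoint and
  KLD the natural-log Kullback–Leibler divergence. A pseudocount of 1e-6
  is added to every entry and the profiles renormalised before the
  computation, so zeros never reach the logarithm and inputs stay on the
  simplex. With natural logs, root-JSD is a true metric bounded by
  sqrt(ln 2) ≈ 0.8326; the bound, the triangle inequality and symmetry are
  property-tested.
* **Bray–Curtis** Σ|a_i−b_i| / Σ(a_i+b_i) and **binary Jaccard**
  1 − |A∩B|/|A∪B| on presence sets.
* **Unweighted and weighted UniFrac**, computed by a single post-order
  pass that accumulates per-branch, per-sample leaf mass in
  O(n_taxa + n_nodes), then compares branch vectors: unique-over-covered
  branch length for the unweighted variant, Σ_b l_b·|A_b − B_b|
  (classic, unnormalised — the QIIME 2 default) for the weighted one.
  Both variants are verified against scikit-bio to 1e-9.

`pairwise` returns an `skbio.DistanceMatrix`, which structurally enforces
symmetry and a zero diagonal.

## Ordination and permutation tests

**NMDS** minimises Kruskal stress-1 by SMACOF majorization with isotonic
regression (non-metric; ties handled by the primary approach). The first
start is initialised from classical metric scaling (PCoA) so one solution
is deterministic and usually near-optimal; remaining starts are random,
and the lowest-stress solution over `n_starts` (default 20) is kept,
centred at the origin.

**PERMANOVA** computes pseudo-F = (SS_between/(k−1))/(SS_within/(n−k))
from squared dissimilarities via the Gower identity (SS_total =
Σ_{i<j} d²/n; within-group sums divided by group size), **ANOSIM**
computes R = (mean between-group rank − mean within-group rank)/(M/2)
over midranked pairs. Both obtain p by label permutation with the
(1 + #{perm ≥ obs})/(1 + n_perm) convention: p = 0 is impossible and the
smallest attainable p is 1/(n_perm+1). The default 999 permutations makes
that minimum 0.001. Permutation statistics are evaluated in a vectorised
batch (one einsum per group over the permutation matrix), which is what
makes thousand-replicate calibration studies affordable.

## Enterotyping

The protocol, end to end: keep the 35 genera with the highest mean
relative abundance (not renormalised — the distance applies its own
pseudocount renormalisation); compute pairwise root-JSD; run PAM at each
k in 2..9; choose the k maximising the Calinski–Harabasz index; validate
with the mean silhouette width; name each cluster by its driver, the
genus with the highest mean relative abundance among the cluster's
samples.

**PAM** is the full Kaufman–Rousseeuw BUILD + SWAP algorithm. BUILD seeds
greedily (first medoid minimises total distance, each subsequent medoid
maximises the cost reduction); SWAP repeatedly applies the single
medoid-for-non-medoid exchange with the largest cost decrease until no
exchange improves, asserting at each step that the cost never rises. Ties
break on the lowest sample index, so the algorithm is deterministic; the
`seed` argument exists only for interface symmetry. SWAP terminates at a
local optimum of total distance-to-medoid: on clusterable data it
coincides with the exhaustive optimum (verified against full medoid-pair
enumeration on 8-point two-cluster instances), but on structureless data
it can legitimately stop short of it — R's `cluster::pam` exhibits the
identical behaviour on the same instances.

**CH index.** The Calinski–Harabasz criterion is usually written in terms
of centroids, which a JSD matrix does not have. The package uses the
pairwise-distance form: W_k = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij,
T = (1/n) Σ_{i<j} d²_ij, B_k = T − W_k, CH = (B_k/(k−1))/(W_k/(n−k)).
In Euclidean space this equals the centroid form exactly (the classical
within-cluster sum-of-squares identity), it operates directly on any
dissimilarity, and it equals the PERMANOVA pseudo-F of the clustering —
hence its value is ≈1 under random labels, which the tests check. A
centroid-on-PCoA alternative is available via `ch_index(..., method="pcoa")`;
no claim is made that either variant matches any particular study's
original scripts.

**Silhouette.** Mean over samples of (b−a)/max(a,b) with a the mean
within-cluster distance (excluding self) and b the smallest mean distance
to another cluster; singleton-cluster members contribute 0. A fit with
mean silhouette below 0.15 sets `weak_structure_`: published enterotype
analyses on real cohorts report mean widths around 0.2–0.3, while truly
structureless compositions score near 0, so 0.15 separates "weak but
present" from "no discrete types" with margin on both sides. The flag is
advisory; the threshold is a constructor argument.

## Association testing

The inclusion filter keeps taxa present in **more than** 10% of samples
with mean relative abundance **above** 0.01% (both strict), the filter
convention of multivariable microbiome association tools. For a
categorical phenotype, `group_tests` runs either a Welch two-sample t per
level pair (pooled-variance optional) or a Kruskal–Wallis omnibus per
taxon, then applies Benjamini–Hochberg across all taxon × contrast
p-values of that phenotype — the adjustment family is per phenotype, a
choice the literature rarely states explicitly; the family is whatever is
passed in one call, so callers wanting a global family can concatenate
first. Welch is the default because cohort phenotype groups are usually
heavily unbalanced.

Tests run on untransformed relative abundances by default, with an
optional log10(x + 1e-6) transform. The choice matters: genus abundances
are zero-inflated and heavy-tailed, and for low-abundance genera the
untransformed Welch t is anticonservative at realistic sample sizes —
on the generator's own null phenotypes its type-I error runs near 7%
rather than 5%, while on the log scale it is calibrated. The calibration
suite therefore exercises the t-test on the log scale; users testing rare
taxa on the raw scale should prefer the Kruskal–Wallis option, whose
calibration does not depend on the abundance distribution.

**Enterotype–phenotype independence** uses the Pearson χ² on the r×c
contingency table (no continuity correction). When any expected cell is
below 5 the asymptotic reference is unreliable, so a seeded Monte-Carlo
p-value (label permutation, +1 convention, default 9999 draws) is
reported instead.

## The synthetic cohort generator

Counts are drawn from a Dirichlet–multinomial mixture: sample an
enterotype from the mixture weights, a composition from that enterotype's
Dirichlet, then reads from a multinomial at a per-sample depth. The
Dirichlet layer supplies the overdispersion real amplicon tables show; the
per-sample depth is uniform on [2000, 20000] so rarefaction has genuine
work to do and under-depth samples are possible by design.

The default spec emulates a two-enterotype healthy-adult cohort: 483
samples over 171 genera, a *Bacteroides*-driven component (weight 0.72,
driver mean abundance 0.38) and a *Prevotella*-driven component (weight
0.28, driver mean 0.40), with the remaining genera sharing a power-law
(rank^−1.3) background — dominant drivers near 40% of the community, a
handful of genera in the 1–10% band, and a long tail of rare genera, the
shape genus-level gut profiles actually have. Within-enterotype dispersion
is a free parameter (cohort studies do not report it): the default
Dirichlet total mass of 50 per component puts the driver's
sample-to-sample standard deviation near sqrt(0.38·0.62/51) ≈ 0.07,
comparable to the spread of dominant genera across real subjects, and
keeps mean within-enterotype root-JSD below the between-enterotype value
— a construction property the test suite asserts directly.

Phenotypes are categorical questionnaire-style variables whose level
frequencies mirror a large published healthy-cohort's margins (gender
65/35, BMI classes 8/73/19, etc.). A *planted effect* multiplies one
taxon's expected relative abundance by a level-specific factor before
renormalisation, keeping compositions valid; a *planted null* is drawn
independently of every taxon and is a genuine negative control. The
default effects are a 2× gender shift on *Blautia* and a 3× diet shift on
*Bilophila*. The gender effect deliberately sits on an abundant,
consistently detected genus: detection power for a fixed fold change
scales with the taxon's baseline abundance relative to its Dirichlet
dispersion, and a 2× shift on a rare zero-inflated genus (α < 1) is not
reliably detectable by a t-test even at n ≈ 500 — a realistic limitation
worth remembering when interpreting negative results on rare taxa.

The random tree generator produces a bifurcating topology by random
sequential pair joining with exponential(0.1) branch lengths (floored at
0.01), sufficient for exercising and cross-validating the UniFrac code;
it does not model real gut-taxon phylogeny.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: sequencing error and chimeras, read-level
structure, taxon–taxon ecological correlations beyond compositional
closure, covariate-correlated phenotypes (planted phenotypes are mutually
independent), batch effects, and longitudinal structure. Recovery results
on this generator are best read as "the machinery is correct and
calibrated", not "real enterotypes are this clean".

## Pipeline and reproducibility

`run_pipeline` executes preprocess → frequency classes → alpha →
distances → NMDS + PERMANOVA/ANOSIM → enterotyping → associations from a
strict YAML config (unknown keys rejected). One master seed spawns an
independent child seed per stage via `numpy.random.SeedSequence`, so
adding a stage never perturbs earlier stages' randomness, and a rerun
with the same config produces a byte-identical `report.json`. The report
is validated against a pydantic schema before writing. Existing artifact
directories are never overwritten without `--force`.

## Problem sizes used in validation

The test suite validates numerics on small instances (6–20 samples) where
brute-force enumeration is exact, runs the full-scale recovery study on
twenty 483 × 171 cohorts, and sizes calibration studies so the asymptotic
tests are exercised inside their validity regime (Kruskal–Wallis on three
groups of 30; χ² at n = 300; PERMANOVA/ANOSIM at n = 20 with 199
permutations, where the permutation p-value grid makes the nominal
rejection probability exactly 0.05; the Welch family on 400 full-scale
null-phenotype cohorts). These sizes are the package's validation
conditions; all are arguments, not constants.

## Known limitations

* PAM's SWAP is a local optimiser (as in every standard PAM); k-scans on
  weakly structured data can select different k across near-tied CH
  values — inspect the full curve, not just the argmax.
* The untransformed Welch t is anticonservative for rare zero-inflated
  taxa (see Association testing above).
* Confounder-adjusted multivariable models (MaAsLin-style) are out of
  scope; only their inclusion filter is provided. Single-factor
  PERMANOVA/ANOSIM only — no multi-factor formulas.
* Weighted UniFrac is the unnormalised classic form; its scale depends on
  tree depth and is not comparable across trees.
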