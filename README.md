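# enterokit

Gut-microbiome **enterotyping and diversity analysis** for genus-level
(or ASV-level) 16S count tables: rarefaction and rare-feature filtering,
detection-rate flora classes, Chao1/Shannon alpha diversity, five
beta-diversity metrics, NMDS with PERMANOVA/ANOSIM, Jensen–Shannon + PAM
enterotyping with Calinski–Harabasz model selection, and taxon–phenotype
association testing with Benjamini–Hochberg FDR control — plus a seeded
Dirichlet–multinomial cohort generator that provides ground truth for
every stage.

The package is aimed at microbiome analysts who want the standard cohort
workflow as tested, composable library code (scikit-learn-style
estimators over pandas DataFrames) rather than a pile of one-off scripts,
and at methodologists who need a calibrated synthetic test bed for
community-typing and association methods.

## The core method

Samples are compared by the **root Jensen–Shannon divergence**, a true
metric on relative-abundance profiles:

```
D(a, b) = sqrt( ½·KLD(p_a, m) + ½·KLD(p_b, m) ),    m = (p_a + p_b)/2
KLD(x, y) = Σ_i x_i ln(x_i / y_i)
```

with a 1e-6 pseudocount (then renormalisation) so zeros never reach the
log. The 35 most abundant genera are clustered by **partitioning around
medoids** (full Kaufman–Rousseeuw BUILD + SWAP) at each k in 2..9, and
the number of enterotypes is the k maximising the **Calinski–Harabasz
index** in its pairwise-distance form

```
CH_k = (B_k / (k−1)) / (W_k / (n−k)),
W_k = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij,   B_k = (1/n) Σ_{i<j} d²_ij − W_k
```

which needs no centroids and therefore works directly on the JSD matrix.
The clustering is validated by the mean **silhouette width** and each
cluster is named after its **driver taxon** — the genus with the highest
mean relative abundance among its samples (classically *Bacteroides* or
*Prevotella* in adult cohorts).

## Worked example

```python
import enterokit as ek
from sklearn.metrics import adjusted_rand_score

# a synthetic two-enterotype cohort: 483 samples, 171 genera,
# Bacteroides/Prevotella components at weights 0.72/0.28
spec = ek.default_cohort_spec(seed=42)
table, meta, truth = ek.generate_cohort(spec, ek.default_planted_effects())

rarefied, dropped = ek.rarefy(table, depth=2000, seed=42)
rel = ek.to_relative(ek.filter_rare_features(rarefied))

result = ek.enterotype_pipeline(rel, seed=42)
print(result.best_k, result.cluster_sizes)
print(result.driver_taxa)
print(round(result.silhouette, 3))
print(adjusted_rand_score(truth, result.labels.to_numpy()))
```

prints

```
2 {0: 348, 1: 135}
{0: ('Bacteroides', 0.3888...), 1: ('Prevotella', 0.4011...)}
0.386
1.0
```

— the CH scan picks two enterotypes (CH₂ = 321.8 vs CH₃ = 167.1), a
*Bacteroides*-driven cluster of 348 samples at 38.9% mean driver
abundance and a *Prevotella*-driven cluster of 135 at 40.1%, and the PAM
labels reproduce the planted partition exactly (adjusted Rand index 1.0).
The mean silhouette of 0.386 says the two types are clearly but not
perfectly separated, as in real cohorts.

Phenotype associations on the same cohort:

```python
from enterokit.association import group_tests, prevalence_abundance_filter

tests = group_tests(prevalence_abundance_filter(rel), meta.loc[rel.index], "gender")
print(tests.nsmallest(2, "q_value")[["taxon", "contrast", "statistic", "q_value"]])
```

```
      taxon       contrast  statistic      q_value
    Blautia Female vs Male  10.470534 2.616007e-21
Bacteroides Female vs Male  -3.547403 1.915522e-02
```

The generator planted a 2× *Blautia* shift in females; the Welch t + BH
machinery recovers it at q ≈ 1e-21 (the secondary *Bacteroides* signal is
the compositional echo of that shift — closure means one genus going up
pushes the others down).

Every stage is also a CLI subcommand (`enterokit synth | preprocess |
alpha | distance | ordinate | betatest | enterotype | associate`), and
`enterokit pipeline run --config config.yaml --outdir out/` drives the
whole analysis from a YAML config to TSV artifacts plus a schema-validated
`report.json` that is byte-identical across reruns with the same seed.

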