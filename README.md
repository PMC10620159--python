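# fritniche

Ensemble species-distribution modelling with niche-overlap, chemical and
phylogenetic comparison, for montane-plant niche studies of the
*Fritillaria* kind — and fully exercisable on simulated ("virtual
species") data with known ground truth.

## What it does

Given species occurrence records and environmental raster layers, the
package runs the standard computational chain of an ecological-niche
comparison across related species:

1. **Occurrence preparation** — thin records to one per 20 km × 20 km grid
   cell, extract environmental values at each point, and pre-filter
   variables: of every pair with |Spearman ρ| > 0.8, drop the one with the
   lower contribution score.
2. **Ensemble SDM** — generate pseudo-absences outside a surface range
   envelope (SRE, a per-variable quantile box), evaluate member models
   (SRE, an IRLS-fitted logistic model with quadratic terms, plus optional
   scikit-learn learners) over repeated stratified train/test splits with
   AUC, TSS = sensitivity + specificity − 1, and Cohen's κ; keep members
   with mean test AUC > 0.9 and combine them as an AUC-weighted mean.
   Project suitability to rasters, derive per-variable response curves,
   suitable ranges (the ≥ 0.5 interval around the optimum), habitat grades
   (not/low/moderate/high at 0.25/0.5/0.75) and spherical areas per grade.
3. **Niche statistics** — Levins breadth B1 (inverse concentration) and B2
   (Shannon uncertainty), Schoener's D and the Hellinger-based I between
   normalized suitability surfaces, the joint moderate-or-better overlap
   region, species-specific habitats, and the overlapping degree
   (A_overlap + B_overlap)/(A_total + B_total) on occurrence records.
4. **Chemical comparison** — 881-bit PubChem-style metabolite fingerprints,
   a Tanimoto similarity network (edge iff similarity > 0.85), metabolite
   groups by connected components or IPCA-style dense-subgraph mining, a
   plant × group incidence matrix, Jaccard/Simpson plant dissimilarities,
   and UPGMA trees with bootstrap support.
5. **Genetic comparison** — pairwise Tamura–Nei (TN93) distances from
   aligned sequences.
6. **Correlation** — Pearson tests (R², two-sided P on n − 2 df) and OLS
   trend lines of niche overlap against chemical dissimilarity or
   evolutionary distance, in the conventional CPD/CPI/CCD/CCI layout.

A synthetic-data module generates every input with known truth: spatially
autocorrelated environmental layers, virtual species with per-variable
Gaussian responses s(x) = Π_k exp(−w_k (z_k − μ_k)² / (2σ_k²)) and
suitability-proportional presence sampling, planted fingerprint clusters
with controlled Tanimoto structure, and alignments evolved under TN93 at a
known branch length (matrix-exponential transition probabilities, exact at
any branch length).

## Worked example

```python
from fritniche.validate import virtual_species_recovery

rep = virtual_species_recovery(seed=1)
print(rep.results.summary())
for var in ("bio01", "bio12"):
    sr = rep.results.suitable_range(var)
    print(f"{var}: suitable range {sr.lo:.2f}-{sr.hi:.2f}, "
          f"optimum {sr.optimum:.2f}")
```

prints

```
Ensemble SDM results
========================================
records: 400 (200 presence)
splits: 0.80 train fraction, 15 runs/algorithm
AUC cutoff for inclusion: > 0.9

member    mean AUC  mean TSS  mean kappa    weight
sre         0.9375    0.8750      0.8750    0.4907
glm         0.9732    0.8667      0.8667    0.5093

bio01: suitable range 10.19-17.96, optimum 14.29
bio12: suitable range 667.71-1120.63, optimum 900.84
```

The virtual species was planted with optima μ = 14.0 (bio01, σ = 2) and
μ = 900 (bio12, σ = 120): both members clear the 0.9 AUC inclusion bar and
the recovered response-curve optima (14.29, 900.84) sit within 0.15 σ of
the truth — the ensemble is reading the species' real environmental
response, not noise.

The whole chain, from simulated rasters to the four-row correlation
report, runs from one config:

```bash
fritniche run --seed 1 --out runs/demo
```

which writes suitability and grade rasters, score/area/breadth/overlap
tables, the Jaccard plant tree (Newick, bootstrap support), TN93 distances
and `correlation_report.csv` into `runs/demo/`, plus `seeds.json` — the
same seed reproduces every file byte for byte.

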