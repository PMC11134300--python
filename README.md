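# microtrans

Quantifying gut-microbiota transmission along social networks and
genealogical lineages in enclosure-housed house mice.

House mice (*Mus musculus musculus*, MMM, and *M. m. domesticus*, MMD) bred
in semi-natural enclosures acquire gut bacteria from their parents, from the
conspecifics they share nest boxes with, and from the shared environment.
`microtrans` takes the three raw observables of such an experiment — an RFID
dual-reader event log, a parentage table, and per-gut-section ASV count
tables — and measures how strongly pedigree relatedness and social contact
predict microbiota similarity between individuals.  A synthetic-population
generator with planted transmission structure makes every stage testable
without access to sequencing data.

## What it computes

- **Social network** (`rfid_social`): nest-box visits are reconstructed from
  the outer→inner / inner→outer reader pattern; the contact between two mice
  is their total co-occupancy time (seconds) in any nest box.
- **Relatedness** (`pedigree_kinship`): the numerator relationship matrix
  *A* by the recursive tabular method — a_ii = 1 + F_i,
  a_ij = ½(a_{j,dam(i)} + a_{j,sire(i)}) — plus dyad classes
  (mother–offspring, full sib, unrelated with r < 0.25, …).
- **Community similarity** (`community_matrix`): technical-duplicate
  merging (an ASV must be detected in both duplicates), rarefaction to the
  minimum depth, Bray–Curtis / Jaccard similarity S = 1 − D, and the logit
  transform used as model response.
- **Dyadic mixed models** (`dyadic_lmm`): for each gut section,
  y_ij = β₀ + β_r·r_ij + β_c·c_ij + u_i + u_j + ε_ij, where the
  multimembership random effect loads on *both* members of every dyad
  (u ~ N(0, σ²_m)).  Estimation profiles the likelihood over
  γ = σ²_m/σ²_e with Woodbury/Sylvester identities, so only q×q linear
  algebra is needed (q = number of individuals).  Backward elimination with
  likelihood-ratio tests, variance partitioning
  (fraction_k = Var(X_k β̂_k) / [ΣVar + 2σ̂²_m + σ̂²_e]), and a close-kin
  exclusion re-analysis are built on top.
- **Per-ASV screens** (`asv_association`): clr-transformed counts → |Δclr|
  dissimilarities per ASV → PCoA with the Cailliez correction → symmetric
  Procrustes m² against the PCoA of the inverted (1 − value) relatedness or
  contact matrix, with permutation p-values and Benjamini–Hochberg FDR per
  (section × subspecies × predictor) family; Spearman/Wilcoxon congruence
  of m² between subspecies.
- **Age trajectories** (`trajectories`): parent–offspring and same-litter
  sibling similarity as a natural-cubic-spline function of offspring age
  inside the same multimembership LMM, complexity chosen by AIC
  (linear vs 2–4 spline df), compared against the population-wide
  unrelated-pair baseline (r < 0.25).
- **Simulator** (`simdata`): demic two-subspecies populations, Poisson
  litters, dual-reader event logs, and multinomial ASV counts whose latent
  compositions mix vertical, social and environmental channels with known
  weights; the vertical weight follows a hump over offspring age (zero
  before weaning, peak in young adulthood, exponential decay).

## Worked example

Simulate one subspecies (80 mice in 6 demes, 120 ASVs), build the contact
and relatedness matrices, and fit the colon dyadic model:

```python
import microtrans as mt
from microtrans import community_matrix as cm, dyadic_lmm as dl, trajectories as tj
from microtrans.simdata import SimConfig, simulate_dataset

config = SimConfig(
    n_founders_per_subspecies=12, max_individuals_per_subspecies=80,
    n_demes=6, n_nestboxes_per_subspecies=6, n_asv=120,
    depth_range=(2374, 20000), visits_per_mouse=150,
    w_vertical=3.0, w_social=3.0, w_env=1.0, sigma_individual=0.4,
    subspecies=("MMM",), sections=("colon",), seed=20,
)
data = simulate_dataset(config)
relatedness = mt.additive_relationship(data.pedigree)
classes = mt.classify_dyads(relatedness, data.pedigree)

depth = int(data.counts.depths().min())
rarefied = cm.rarefy(data.counts, depth, seed=20)
similarity = cm.logit_similarity(cm.dissimilarity(rarefied, "bray_curtis"))

dyads = dl.build_dyads(similarity, data.meta, relatedness, data.contacts,
                       dyad_classes=classes, section="colon")
report = dl.lrt_and_stepwise(dyads, ("relatedness", "contact"))
fit = dl.fit_mm_lmm(dyads, ("relatedness", "contact"))
print(dl.variance_partition(fit, dyads).round(4))
```

Output:

```
rarefaction depth: 2491
dyads: 3160 (colon, within-subspecies)
       term  lrt_chi2  df  p_value  retained
relatedness   17.9559   1      0.0      True
    contact   48.2704   1      0.0      True
relatedness    0.0036
contact        0.0092
member         0.4360
residual       0.5512
unrelated baseline (logit similarity): 2.014 [1.990, 2.039]
```

Both predictors are retained by the stepwise likelihood-ratio procedure;
relatedness and contact together explain ~1.3% of the response variance in
this configuration, the rest being split between individual (member) and
residual variance.  The baseline is the mean logit Bray–Curtis similarity
among unrelated pairs, the reference that kin trajectories are compared to.

The same analyses run from the shell:

```bash
microtrans simulate --out sim/ --seed 1          # uses the shipped scenario
microtrans social sim/events.csv --pedigree sim/pedigree.csv --out contacts.csv
microtrans kinship sim/pedigree.csv --out relatedness.csv
microtrans run --config run.yaml                 # full pipeline with manifest
```

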