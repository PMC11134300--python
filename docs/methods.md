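# Methods

## The inference problem

Each mouse contributes one terminal sample per gut section (ileum, cecum,
colon).  Pairwise microbiota similarity between individuals is the response;
pedigree relatedness and social contact are the predictors.  Because every
individual appears in many dyads, pairwise values are not independent: the
models therefore carry a multimembership random effect in which each dyad
loads on both of its members with weight 1 and a single variance component
σ²_m is shared by all individuals.

### Dyadic mixed model

For dyad (i, j): y_ij = x_ij'β + u_i + u_j + ε_ij with u ~ N(0, σ²_m I),
ε ~ N(0, σ²_e I).  Writing V = σ²_e (I + γ ZZ') with γ = σ²_m/σ²_e and Z the
n×q two-hot membership matrix, the profiled −2·log-likelihood (ML or REML)
is minimised over log γ by bounded Brent search and compared against the
γ = 0 boundary.  All solves use the Woodbury identity through the q×q Gram
matrix Z'Z and Sylvester's determinant identity, so a fit costs O(nq + q³)
— a few milliseconds for 150 individuals and 11 175 dyads.  Convergence is
to a relative criterion change below 1e−8 (the Brent tolerance is stricter).
Fixed-effect tests are likelihood-ratio χ² on ML fits; variance components
are reported from REML fits; no Satterthwaite degrees of freedom are
computed.  Backward elimination removes, per round, the least significant
removable term with p ≥ 0.05, never removing a main effect while its
interaction remains.

Variance partitioning attributes Var(X_k β̂_k) (empirical variance over the
dyads) to each fixed term; the member effect contributes 2σ̂²_m because each
dyad carries two member effects; fractions are normalised to sum to one.

### Similarity responses

Counts are rarefied once to the minimum sample depth (multivariate
hypergeometric draw), similarities are S = 1 − D for Bray–Curtis (relative
abundances) or Jaccard (presence/absence), and the response is
logit(S) after a symmetric squeeze into [eps, 1−eps], eps = 1e−3.  The
similarity orientation (rather than dissimilarity) only flips coefficient
signs.  Phylogenetically weighted metrics are deliberately not offered:
shared dispersal-relevant traits of related bacteria are part of the signal
of interest, and down-weighting closely related ASVs would suppress it.
Contact seconds are min–max scaled to [0, 1] within subspecies before
entering the model (a log(1+s) alternative is available); relatedness is
clipped to [0, 1] so that the 1 − r inversion used by the ordination stays
in range.

### Per-ASV screens

Counts + 0.5 pseudocount → clr; per ASV the |Δclr| line metric between
samples; PCoA with the Cailliez additive constant (computed from the 2n×2n
special eigenproblem) whenever the Gower-centred matrix has eigenvalues
below −1e−8 × λ_max; axes with eigenvalue above 1e−8 × λ_max are retained.
Predictor matrices are normalised, inverted (D = 1 − M) and embedded the
same way.  The symmetric Procrustes statistic m² = 1 − (Σ singular values)²
is computed after centring and scaling both configurations to unit sum of
squares and zero-padding the narrower one; the permutation p uses the
(1 + #{m²_perm ≤ m²_obs}) / (1 + N) estimator (N = 999 by default) so p is
never zero before BH-FDR.  FDR families are per
(section × subspecies × predictor), matching how counts of significant ASVs
are reported.

### Age trajectories

Parent–offspring (and same-litter sibling) logit similarities are modelled
as natural cubic splines of offspring age inside the same multimembership
LMM, with parent and offspring (or the two siblings) as members.  The basis
is the truncated-power natural-spline construction with df ∈ {2, 3, 4}
columns, interior knots at age quantiles and boundary knots at the age
range; extrapolation is exactly linear.  Candidates (linear, ns2–ns4) are
compared by ML AIC counting fixed effects plus both variance components.
Prediction bands are delta-method 95% intervals on the fixed-effect
covariance (a bootstrap is intentionally not the default: deterministic and
cheap).  The population baseline is an intercept-only multimembership fit on
dyads with r < 0.25 (strict inequality; threshold configurable).  The
trajectory-versus-baseline report uses the CI non-overlap rule and the age
of maximal fitted similarity.

## The synthetic-data generator

The generator emulates the enclosure experiment: founders released as
adults into demes, Poisson litters (mean 6) with within-deme sires chosen
with probability `p_within_deme_mating`, no cross-subspecies matings, birth
dates spread across a ~270-day experiment, all animals sampled at the end
(age at sampling = experiment end − birth day).  Movement is simulated as
non-overlapping nest-box visit bouts with a configurable own-deme
preference, emitted as the four-read dual-antenna pattern with optional read
dropout.

Latent compositions mix three channels per ASV:

λ_i = [w_v(age_i)·½(λ_dam + λ_sire) + w_s·(contact-weighted partner mean)
      + w_e·(λ_env + ε_i)] / (w_v + w_s + w_e)

iterated for 3 synchronous rounds in birth order so influence propagates
along the network; founders initialise at λ_env + ε.  Individual noise ε_i
(SD `sigma_individual`, log scale) enters through the environmental channel:
this makes the weights meaningful — an ASV with a dominant social weight
tracks its donors instead of retaining full idiosyncratic noise, which is
what "transmitted" has to mean for any downstream signal to exist.  The
vertical weight w_v(age) is 0 before weaning (23 d; milk-shaped communities),
rises linearly to its maximum at 65 d (dispersal from the parental
territory) and decays exponentially at 0.04/d afterwards, placing the return
to baseline near 100 d of age, consistent with the reported timeline of
parental-effect decay.  Sections share one latent composition; the ileum
applies a sparsification mask keeping ~5% dominant ASVs at full weight
(low small-intestine diversity), cecum and colon are unmasked.  Counts are
multinomial at a uniform random depth; the shipped scenario uses depths
2 374–45 661 and 500 ASVs over ~100 mice per subspecies.

What the generator does **not** emulate: sequencing-error/chimera processes
(counts are generated at the ASV-table level), hybridisation between
subspecies, seasonal or dietary variation, spatial environmental gradients,
mortality, and repeated sampling of an individual over time.  Passing tests
therefore demonstrate correctness of the estimators under a known
transmission process, not robustness to those real-data complications.

## Validation design and problem sizes

- Kinship: tabular A vs an independent recursive path-counting kinship on
  all 5 184 sex-consistent six-individual pedigrees (exhaustive over every
  dam/sire choice) plus random ten-individual pedigrees, exact to 1e−12;
  gene-dropping Monte Carlo (1e5 drops) on a full-sib-mating pedigree within
  3 SE.
- REML: sparse criterion vs dense-matrix likelihood on a γ grid, ≤ 12
  individuals, within 1e−6.
- Procrustes: m² vs a 30 000-step rotation(+reflection) grid on 2-D
  five-point instances within 1e−4; exact 0 under similarity transforms.
- Null calibration: 200 null simulations (25 individuals) give LRT
  rejection within the binomial band around 5%; 200 Procrustes permutation
  p-values pass a KS uniformity check; 20 all-null screens stay at or below
  5% significant calls.
- Recovery: β = (1, 0.8), σ²_m = σ²_e = 1 at 150 individuals over 50
  replicates within 10%; a planted 10% relatedness variance fraction within
  the Monte-Carlo CI.
- Planted signals: 10 socially transmitted ASVs (w_s = 4 vs 0, 36 mice in
  12 small demes) enriched among FDR calls (hypergeometric p < 0.01); the
  65-day vertical hump recovered with fitted peak in [60, 80] d in ≥ 8/10
  replicates (~150–250 parent–offspring pairs each).
- Structural contrast: paired demic (p_within = 0.95, preference 0.95) vs
  panmictic (p_within = 1/6, preference 0) scenarios at 80 mice; the
  combined relatedness+contact variance fraction is larger under demic
  structure in ≥ 8/10 pairs.

These sizes were chosen as the smallest configurations at which the planted
effects are identifiable with comfortable margins.

## Numerical and design choices

- Visit reconstruction anchors start/end at the inner-reader timestamps; an
  outer read observed mid-visit signals a lost exit pair, so the open visit
  is dropped and the read treated as a candidate entry (greedy
  resynchronisation; the parse report quantifies loss).  Overlapping raw
  visits of one mouse in one box are unioned before intersection so
  co-occupancy is never double counted.
- Exact duplicate event records are removed silently but counted.
- Unknown parents contribute zero in the tabular method; one-known-parent
  rows use the known side only.
- clr zero handling uses a global 0.5 pseudocount.
- Rarefaction below threshold errors by default (`on_shallow="drop"` opts
  into dropping with a warning); it is performed once per seed, not
  averaged.
- All randomness derives from one integer seed through CRC32-keyed named
  substreams, so stages are independently reproducible and byte-identical
  across re-runs.
- Pipeline stages re-run when an output is missing or an input is newer
  than its outputs (make-style), so deleting an intermediate regenerates
  only its stage and the stages downstream.

## Known limitations

- The LMM assumes a single member variance component; sex- or
  subspecies-specific member variances are not modelled.
- Permutation p-values are exchangeable-row tests; no restricted
  permutation within subspecies/deme strata is offered.
- Cross-subspecies dyads enter only the pooled interaction model; the
  within-subspecies models never mix enclosures.
- The tunnel between enclosures is not part of the contact definition, and
  no network-modularity statistics are computed here.
- Alpha diversity is out of scope by design.
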