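# Methods

`complexmap` turns heterogeneous protein-observation experiments —
affinity-purification / proximity-labeling pull-downs and co-fractionation
elution profiles — into a confidence-ranked map of protein complexes. This
note records the models, conventions and numerical choices behind each
stage, and what the synthetic benchmark does and does not demonstrate.

## Co-occurrence scoring: the weighted matrix model

A compendium of N experiments is reduced to presence/absence calls
(a protein is present when its abundance strictly exceeds a per-dataset
cutoff; the `"all"` sentinel counts any observation). For a pair of
proteins seen in n and m experiments respectively, and together in k, the
evidence of association is the hypergeometric upper tail

P(#shared ≥ k | n, m, N) = Σ_{i=k..min(n,m)} C(n,i) C(N−n, m−i) / C(N,m).

Conditioning on the marginals n and m is the model's entire defense
against "frequent flyer" proteins: a sticky pair needs far more shared
experiments to achieve the same surprise. No further correction is
applied. Two features are emitted per pair and cutoff: −ln p and the raw
pair count k. The tail is evaluated with `scipy.stats.hypergeom.logsf`
(never leaving log space); k = 0 returns exactly p = 1, and −ln p is
clipped at 0 against −0.0 round-off. The implementation is verified
against exhaustive placement enumeration for all parameter combinations
with N ≤ 12 at 1e-10 relative tolerance.

Presence cutoffs default to {any observation, > 2, > 4}, producing
separately named feature columns per cutoff. Comparisons are strict (>),
so a score exactly at the cutoff is absent.

## Co-fractionation similarity measures

Four pairwise measures summarize co-elution. Their classical originals
are defined in the co-fractionation literature; the functional forms here
are package conventions chosen to preserve each measure's role:

- **Poisson-noise Pearson** — mean Pearson correlation over `n_repeats`
  (default 10) resamples where each entry is redrawn from
  Poisson(value + pseudocount), pseudocount 1. Robust to sparse-count
  noise. Zero-variance resamples are skipped; if all repeats degenerate
  the score is undefined (emitted as 0 in feature fragments). The RNG is
  keyed per pair by a CRC of the sorted accessions plus the base seed, so
  feature values are reproducible and order-independent.
- **Weighted cross-correlation** — max over lags |ℓ| ≤ 3 of
  Σ_t a[t]b[t+ℓ] / (‖a‖‖b‖), down-weighted by 1/(1+|ℓ|). At lag 0 this is
  cosine similarity; small elution shifts are tolerated but penalized.
- **Co-apex** — 1/(1 + |Δ argmax|); argmax ties resolve to the earliest
  fraction.
- **MS1 intensity similarity** — 1 − ½‖a/Σa − b/Σb‖₁, i.e. one minus the
  normalized L1 distance between fraction-normalized profiles, in [0,1].

A cross-species support filter keeps a pair when at least 2 species have
any measure strictly above 0.5 (any-measure semantics).

## Feature assembly and labeling

Fragments are outer-joined over the union of canonical (lexicographically
ordered) pairs; absent cells are semantically 0.0 — sparse evidence over
a large pair universe densified for the classifier. Assembly is
order-independent (sorted columns, lexicographic pairs); conflicting
duplicate values for the same (pair, column) are an error. Gold-standard
labeled pairs missing from every fragment are added as all-zero rows so
the classifier and the PR evaluation see them; dropping them would bias
precision-recall upward.

## Gold standard construction

Literature-style complex lists are de-redunded by repeatedly replacing
the highest-Jaccard pair of complexes above the merge threshold (default
0.6, strict >) with its union; processing in descending-Jaccard order
makes the fixed point independent of input order, and the operation is
idempotent. Complexes are then shuffled (split seed, default 1234) and
assigned alternately to train/test; a complex whose within-complex
*pairs* overlap pairs already assigned to the other split is dropped
(the later-assigned complex loses) — the leakage unit for a co-complex
classifier is the pair, not the complex. Complexes above 30 subunits are
removed by default; an optional flag additionally drops the single
largest complex.

Positives are within-complex pairs of a split; for complexes above the
size threshold only a fraction (default 0.1) of pairs is kept, flooring
the count, with a dedicated RNG stream. Negatives are cross-complex
pairs among the split's proteins that are co-complexed nowhere in the
full gold standard; everything else stays unlabeled. Test-side labels
exclude any pair already labeled for training, keeping the splits'
labeled sets disjoint (asserted again at evaluation time).

## Co-complex classifier

An RBF-kernel SVM classifies labeled pairs. C and gamma are selected by
stratified, seeded k-fold (default 5) cross-validation maximizing the
area under the precision-recall curve — the appropriate criterion under
heavy class imbalance since it ignores true negatives. The default grids
are C ∈ {2, 8, 32, 128, 512} and
gamma ∈ {0.00048828125, 0.001953125, 0.0078125, 0.03125}; ties break
toward the smaller (C, gamma). Features are standardized column-wise on
training rows only (fit per fold inside CV). The chosen model is refit
on all labeled pairs and converted to probabilities by Platt sigmoid
calibration (`CalibratedClassifierCV`, `ensemble=False`, 3-fold);
constant feature columns are dropped with a warning, and a matrix with
no informative column yields a uniform score equal to the positive
fraction. Scores are written at full float precision: rounding near-1
probabilities to a fixed number of decimals would alias them onto the
sweep's extreme threshold and fabricate an elite edge set.

Evaluation restricts to held-out labeled test pairs: a standard PR curve
with average precision, plus a score→empirical-precision calibration
table over a descending threshold sweep.

## Two-stage clustering

1. **Threshold** the scored network at t (edges with score ≥ t;
   isolated nodes drop out).
2. **Greedy cohesiveness clustering** of the *unweighted* graph
   (ClusterOne-style). Cohesiveness of a node set V is
   f(V) = w_in / (w_in + w_bound + p·|V|) with penalty p = 2 and unit
   weights. Seeds are visited in descending degree order, skipping
   covered nodes; growth/shrinkage accepts only strict cohesiveness
   increases (the seed node is never removed). Overlapping clusters with
   ω = |A∩B|²/(|A||B|) ≥ max_overlap are unioned to a fixed point (each
   merge round strictly reduces the count, so this terminates). Clusters
   below the density threshold (2E/(|V|(|V|−1))) or below 3 members are
   discarded. Seed order, strict-increase acceptance and the penalty
   default are re-implementation conventions following the published
   algorithm description.
3. **Markov clustering** of each dense region's *weighted* subgraph.
   Self-loops get the node's maximum incident weight (standard MCL
   practice); the column-stochastic flow matrix is iterated — expand
   (matrix square), inflate (entrywise power, renormalize), prune
   (entries < 1e-5, renormalize) — until the max entry change is < 1e-6
   (cap 100 iterations, warning on non-convergence). Clusters are the
   connected components of the limit flow's support. Columns are
   renormalized after every inflation, so stochasticity holds to 1e-9 by
   construction (asserted in tests).
4. **Post-filter**: members with no within-cluster edge scoring at or
   above the threshold are removed; clusters below 2 members drop. The
   filter uses ≥ (consistent with edge retention) — a strict > would
   empty every cluster whenever the maximum score equals the threshold.

The parameter sweep evaluates every combination of the grids
(21 thresholds from 1.0 down to 1e-5; densities 0.1–0.4; max overlap
0.6–0.8; inflation 1.2–15; 2,835 combinations in the packaged defaults)
with the weighted k-clique precision/recall against the *training*
complexes, sharing the ClusterOne stage across inflations. Five
parameter sets are then selected along the precision-recall Pareto front
(deterministic even sampling from the highest-precision end — a
codification of the by-eye trade-off selection the workflow calls for)
and their clusterings are unioned. An identical member set appearing in
several tiers keeps its highest tier (ExtremelyHigh … Medium);
near-duplicates are all retained, since no fuzzy deduplication is
specified at union time. The packaged `DEFAULT_SELECTED_PARAMS` carry
the five confidence-ranked parameter sets used for the published
full-scale map (tier 1: threshold 1.0, density 0.4, overlap 0.6,
inflation 9).

## k-clique precision/recall

For clique sizes k = 2 … (largest complex), every size-k subset of a
predicted cluster is tested for containment in some gold complex
(precision) and vice versa (recall); gold complexes are treated as
complete cliques. Per-k values aggregate as weighted means with weight
#{complexes on that side with size ≥ k} — precision always weights by
clusters; recall weights default to the gold side, with a cluster-side
switch, because the defining sentence is ambiguous about the recall
weight (reports surface which weighting was used). Enumeration switches
to seeded uniform sampling above 10,000 subsets per (side, k), allocated
per complex proportionally to its C(size, k) count. A side with no
complex of size ≥ k is undefined at that k and excluded from its
aggregate. The implementation is checked exactly against a brute-force
subset-containment oracle on random fixtures, and sampled mode against
the exhaustive value within three standard errors.

## Post-analyses

- **Subcomplex index** SC(A,B) = |A∩B|/|A| — asymmetric, 1 when A ⊆ B.
- **Non-redundant set**: greedy pass in confidence-tier order, then size
  descending, then lexicographic; a candidate is kept only if SC in both
  directions against every kept complex is < 0.5. The greedy order makes
  the result deterministic; a symmetric variant (drop any complex with
  SC ≥ 0.5 versus any other, which can empty mutually redundant groups)
  is available behind a switch.
- **Promiscuous proteins**: members of ≥ 2 complexes of the non-redundant
  set, with membership counts.
- **Protein-age z-scores**: observed per-age-group promiscuous counts
  versus the mean/SD of resampled draws (|promiscuous| proteins, without
  replacement) from the non-promiscuous background. Note the null
  distribution of these z-scores is over-dispersed relative to N(0,1)
  when the background is small (the observed draw and the background are
  complementary), but it is unbiased; tests therefore check the signed
  mean across seeds, not |z|.
- **Annotation enrichment**: per (complex, term) hypergeometric tail
  with N = |background|. The significance threshold is empirical: the
  largest p at which membership-shuffled complexes (shuffles preserve
  cluster count, size distribution, and each protein's membership
  multiplicity) are flagged at a rate ≤ α times the real rate (default
  α = 0.05, 20 shuffles). Benjamini–Hochberg is available as a flag.

## Synthetic benchmark

The generator plants complexes (sizes uniform in a range; a configurable
fraction share exactly one member with an earlier complex, creating
promiscuity), then simulates:

- **Pull-downs**: one bait per experiment cycling round-robin over a
  seeded shuffle of all complex members (so small runs cover every
  complex); co-complex partners detected with probability
  `member_detect_prob`; Poisson(`contaminant_rate`) spurious proteins
  drawn uniformly from the whole proteome, complex members included —
  deliberate "frequent flyer" pressure that exercises the WMM's
  marginal conditioning. Abundances are shifted log-normal
  (1 + LogNormal(1.0, 0.9)), so the >2 / >4 presence cutoffs split the
  distribution non-trivially.
- **Elution profiles**: one shared Gaussian peak center per complex;
  member rows are the peak times a per-protein amplitude with
  multiplicative log-normal noise; multi-complex proteins sum their
  peaks; background proteins get independent centers.

Reference study conditions (the pipeline and acceptance defaults):
30 complexes of 3–8 subunits, overlap fraction 0.2, 100 background
proteins, 400 pull-downs at detection probability 0.9 with 2
contaminants/experiment, 60 fractions with relative elution noise 0.1.
These sizes keep a full end-to-end run under a minute on one CPU; the
demo sweep grid (6 thresholds × 2 densities × 2 overlaps × 3 inflations)
is a subset of the full packaged grids, which remain the default for
`parameter_sweep` itself.

What passing on this benchmark does **not** show: the generator has no
peptide-level noise, no ortholog structure, no bait-specific abundance
biases, and far less complex-size and coverage heterogeneity than real
compendia. In particular the classifier is near-perfect here (test AUPRC
≈ 1), so the benchmark validates the *machinery* — leakage-free
splitting, calibrated scoring, clustering recovery, metric correctness —
not real-data accuracy. One scale artifact is worth knowing: the sweep
evaluates against the training half of the gold standard, so a
clustering that recovers *all* planted complexes caps at ≈ 0.6 k-clique
precision against that half (every test-half recovery counts against it);
on real data the gold standard is a small sample of truth and the effect
is milder.

## Determinism

One top-level seed derives each stage's seed as
`(seed · 1000003 + stage_offset) mod 2³¹`. All set-valued intermediates
are sorted before RNG consumption or output, gzip members are written
with mtime 0, and scores print at full float precision — two runs with
the same seed are byte-identical, independent of `PYTHONHASHSEED`.

## Known limitations

- ClusterOne and MCL are faithful re-implementations, not bindings to
  the reference binaries; minor tie-breaking differences from the
  originals are possible (an adapter seam exists but is untested against
  the binaries).
- The co-fractionation measures approximate the classical definitions;
  they are not numerically comparable to values produced by the original
  tooling.
- Annotation terms are flat sets (no ontology propagation), and the
  empirical-FDR threshold is a global scalar, not per-category.
- The greedy non-redundant set depends on the tier ranking; the
  symmetric variant can discard every member of a mutually redundant
  group.
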