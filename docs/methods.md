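# Methods

## Overview

`cnvprior` decides whether a copy number variant (CNV) is clinically
harmful for the patient in whom it was observed. It layers two
classifiers: a gene-level Random Forest over ontology-derived function
features and patient phenotype indicators, whose per-gene "causative"
calls are OR-combined into a per-CNV flag; and a CNV-level Naive Bayes
over that flag, the CNV's length, and its overlap with catalogs of
variants seen in presumed-healthy individuals. The design assumes that
(a) harmfulness is mediated by at least one gene inside the CNV,
(b) gene function plus interaction context carries signal about which
gene that is, and (c) prior gene–phenotype knowledge, while incomplete,
is informative when weighted by ontology similarity.

## Ontology similarity

Both the gene-function and the phenotype ontology are treated as DAGs
of terms under `is a` edges; other relation types are ignored.
Annotations are propagated to all ancestors before computing term
frequencies, so the information content `IC(t) = −ln freq(t)` is
monotone non-increasing toward the root. Similarity between term sets
is Resnik-style through the most informative common ancestor:

    sim(X, Y) = avg_{x∈X} max_{y∈Y} IC(MICA(x, y))

Numerical and degenerate-case choices:

- **Log base**: natural log. All uses are comparative (max/avg), so the
  base is a global rescale only.
- **Terms annotating zero targets** have undefined frequency; they are
  excluded from MICA candidacy, and a pair with no informative common
  ancestor contributes 0 ("no evidence"). The scalar accessor returns a
  `NO_INFORMATION` sentinel rather than a silent 0.
- **MICA ties** break to the lexicographically smallest identifier;
  only the IC value is consumed downstream, so the choice is cosmetic
  but keeps runs reproducible.
- **Empty sets** score 0 (the average over an empty set is undefined).
- The measure is **asymmetric** (averaged over the first argument) and
  is used exactly in that form; a `symmetrize` flag exists but defaults
  off.
- **Multi-rooted ontologies** are treated as forests; cross-namespace
  pairs contribute 0.

## Network neighborhoods

The interaction network (weighted edge list; duplicate pairs summed) is
filtered to the strongest fraction of edges — default 0.05, i.e. the
top 5% of a dense genome-scale composite network. Edges become
distances `d = max_w / w ≥ 1`; per query gene, Dijkstra's algorithm
selects the 30 nearest neighbors. Edges severed by the cut are
replaced by a sink node per boundary gene, weighted by the sum of that
gene's removed edges, so leaked probability mass is modelled.

Neighbors are ranked by a **random walk with restart** at the query:
transition probabilities are row-normalized edge weights over the
subnetwork (sink included), restart probability α = 0.5, power
iteration to L1 change < 1e−9 (cap 10,000 iterations, failure raises).
The form of the walk is a package choice — restart guarantees a unique,
query-centred stationary distribution and prevents the sink from
absorbing all mass; α and the tolerance are configurable. The sink is
an ordinary bidirectional node: never ranked, never a feature source.
Rank ties break by ascending Dijkstra distance, then identifier. Genes
absent from the filtered network, or isolated, get an empty
neighborhood and contribute only their own annotations.

## Feature construction

Raw annotations map to their nearest slim ancestors (all minimal-
distance slim terms are kept on ties, map2slim-style; terms with no
slim ancestor contribute nothing). Evidence codes partition into
tier 1 (experimental: EXP, IDA, IPI, IMP, IGI, IEP, TAS, IC), tier 2
(computational/inferred: ISS, ISO, ISA, ISM, IGC, IBA, RCA, IEA), and
ignored (no traceable source: ND, NAS, NR); unrecognized codes are
conservatively treated as tier 2. Per (gene, slim term) only the best
tier survives, so redundant annotation rows are never double-counted.

The network-weighted value of feature `f` sums `10^(−r) · 10^(−e)` over
the query gene (r = 0) and its top-k ranked neighbors (k = 10 by
default; the contribution set is the reconciliation of the weighting
formula, which runs over the subnetwork, with the neighbor-count sweep
that selects 10). The query gene's own annotations pass the same
evidence damping as neighbor annotations — the formula implies it.
The uniform scheme assigns 1 to any feature seen in the same
contribution set.

## Phenotype relevance and copy weights

Relevance multiplies gene-function similarity with phenotype
similarity, maximized over the catalog. The fallback for
zero-relevance genes takes the best *direct* neighbor score scaled by
`1/d ∈ (0, 1]` — the normalized form of the inverse-distance weight —
so a fallback can never exceed the neighbor it borrows from; it is one
hop deep, never recursive, and consults all subnetwork members
(configurable). Copy counts use the ceiling formula with 1000 copies
per CNV; the ceiling can overshoot by at most one copy per gene, and a
gene with zero relevance inside a CNV with positive total gets zero
copies (the limit of the formula). Copies are materialized by row
replication in the training matrix.

## CNV features

Coordinates are 0-based half-open; `length = end − start`. Gene
assignment uses any overlap ≥ 1 bp (the standard interval-intersection
default; no fraction is imposed for genes). The benign-overlap score
merges regions within each study (overlapping or touching intervals
unify), then sums, over all studies, the fractional overlap of every
merged region covering ≥ 50% of the CNV's length — exactly 50%
qualifies. The score is type-agnostic by default (a type-matching flag
exists but is off): deletion/duplication matching against the benign
catalogs is not attempted. CNV type is carried through but is *not* a
classifier feature; the CNV classifier sees exactly the causative flag,
length, and the overlap score.

## Classifiers

- **Gene layer**: Random Forest, 100 trees, √(#features) per split, no
  depth cap, seeded per run. Hyperparameters follow common defaults of
  the era of desktop ML toolkits and are configurable.
- **CNV layer**: Naive Bayes with a Laplace-smoothed Bernoulli
  likelihood for the causative flag and Gaussian likelihoods for
  log10(length) and the overlap score (variance floor 1e−9 for constant
  features). Lengths behave far better on a log scale. Any subset of
  the three features can be selected for ablation.
- Single-class training inputs are rejected at both layers.

## Evaluation protocol

Per run: a three-pool split (gene-train 50%, gene-test/CNV-train 25%,
CNV-test 25%), gene model fit on replicated rows, causative flags
computed for the middle pool, Naive Bayes fit, metrics on the final
pool. The *balanced* regime sweeps phenotypes in order of decreasing
case count, repeatedly drawing two cases and two controls per
phenotype until exhausted, and distributes each quad so every pool
keeps a 1:1 class ratio; CNVs never drawn are left out of that run.
The *unbalanced* regime assigns whole patients to pools targeting the
50/25/25 CNV-count proportions, preserving the natural benign excess.
Metrics are computed per run and then averaged (not pooled); run *i*
uses seed *i* unless a base seed or explicit seed list is configured.
Precision with zero predicted positives is reported as 0 with an
`undefined_precision` flag.

## Synthetic study conditions

The generator (`cnvprior.simulate`) emulates every external resource at
toy scale. Fixed design choices:

- Gene-function ontology of 60 terms with an 11-term slim layer under
  the root and diamond (multi-parent) structure below; phenotype
  ontology of 24 terms with 20 annotated disorders.
- 80 genes on 4 chromosomes of 10 Mb; 8 disease genes annotated below
  3 planted slim terms (round-robin across the planted branches so each
  carries mass), wired into a strong interaction module with hub-like
  edges to bystander genes — the contamination that motivates rank
  damping.
- 64 CNVs from 32 patients. Harmful CNVs cover a disease gene with
  probability `effect_strength` (0.95 by default); all other CNVs are
  placed over ordinary genes (10% in gene deserts) and avoid disease
  genes, so `effect_strength` is the *only* coupling between planted
  genes and labels. Harmful lengths are log-normal with median
  ~250 kb vs ~30 kb benign, mirroring the qualitative length–harm
  relationship in clinical cohorts. Three benign-region studies cover
  benign CNVs with probability 0.9 each and harmful CNVs with 0.05.
- The catalog links disease genes to the cohort's phenotype terms plus
  uninformative decoy entries, making phenotype relevance informative.
- The default benign:harmful ratio is 15:1 (the clinical excess); the
  planted-recovery experiments use a 1:1 cohort.
- `experiment_config()` adapts two parameters to the toy scale: the
  edge filter is 0.5 (the generated interactome is already sparse,
  unlike a dense genome-scale composite network, so top-5% filtering
  would destroy it) and 50 trees (ample for ~14 features). Everything
  else keeps the canonical defaults.
- A separate clinical-scale table generator emulates a diagnostic
  cohort's *shape* only (2,643 CNVs, 162 harmful, 140 patients,
  phenotype composition dominated by developmental delay); it exercises
  the dataset reader, nothing downstream.

What passing synthetic experiments show — and what they do not: the
pipeline recovers a planted function→harmfulness signal with mean
F ≥ 0.9 and near-perfect recall, loses it under label permutation, and
assigns the planted features no systematic importance excess when the
effect is switched off. They do *not* demonstrate clinical-grade
precision/recall: real resources are orders of magnitude larger, gene
reuse across CNVs is lower, annotation noise is structured rather than
uniform, and array breakpoint imprecision is not modelled. At toy
scale the forest partially memorizes the few recurring disease genes,
which flattens the differences between the feature- and gene-weighting
schemes (they tie near the performance ceiling rather than separating
as they would on large cohorts); the gene-feature-only ablation
separates them more visibly.

## Known limitations

- No liftover, no CNV calling, no breakpoint refinement; inputs are
  assumed to share one assembly and the BED convention.
- The catalog fallback is single-hop; deeply isolated genes with no
  informative neighbors simply score zero.
- The OR combination of gene calls deliberately overcalls (it
  maximizes recall at the cost of precision); probabilistic gene
  combination is out of scope.
- Naive Bayes numeric likelihoods are Gaussian; a kernel-density
  option is not implemented.
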