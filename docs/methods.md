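# Methods

This note documents the models and procedures implemented in
`ricepangenes`, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Pangene clustering

Clustering consumes *correspondences*: edges between genes in different
genomes, each carrying the fraction of the shorter gene covered by the
whole-genome-alignment overlap and a same-strand flag.  Producing these
edges (alignment, interval intersection) is upstream of this package.

Edges with `overlap_fraction < min_overlap` (default **0.5**, mirroring
the annotation-merge threshold) or `same_strand = false` are discarded.
The survivors are processed in descending overlap order — ties broken
lexicographically by `(gene_a, gene_b)` so the result is independent of
input order — and united with a disjoint-set structure under a **conflict
veto**: an edge is skipped if its union would put two genes that
physically overlap on opposite strands *within one genome* into one
cluster.  The veto granularity (higher-overlap edge wins, because edges
arrive in descending overlap order) is this package's resolution of the
stated constraint; the constraint itself says only that opposite-strand
overlapping genes must never co-cluster.  Genes with no surviving edge
become singleton pangenes.  Multiple genes of one genome may co-cluster
(within-genome paralogs share a matrix cell).

Matrix rows are ordered by the genomic position of each cluster's
left-most member (normalized chromosome number, then start, then gene
id), which makes row order — and therefore serial-number assignment —
stable and reproducible.

**Occupancy classes.**  For panel size N: core = N; cloud ≤ 2; softcore =
⌊0.95·N⌋ … N−1 (15 of 16); shell otherwise.  The floor (rather than
ceiling) reading of "95 % of genomes" is forced by the 16-genome case,
where softcore is explicitly occupancy 15.

## Annotation merging

Reference genomes often carry several annotation tracks (here: RAP-DB,
a pipeline-generated OsNip set, MSU).  Only protein-coding genes (≥ 1
transcript with CDS) participate.  Two genes merge when same-strand
ranges on one chromosome overlap by ≥ 50 % of the shorter gene, measured
on the *original* ranges; merged genes are the connected components of
this relation.  Component (transitive) merging is the only
order-independent reading when chains A–B–C occur with A and C disjoint,
and is what the implementation does.  The merged span is the extreme
5′/3′ extent of the members; the merged id is the highest-priority
member's id (RAP-DB > OsNip > MSU, configurable).  MSU TE-tagged models
are retained and flagged at merge time; TE filtering is an explicitly
occupancy-dependent later step (below).

## Stable identifiers

`[clade].[group].[version].panDDDDDDD`, e.g. `Os4530.POR.1.pan0000001`:
clade is a one/two-letter code plus NCBI taxon id, group a three-letter
consortium code, version ≥ 1.  The first of the seven digits is the
series: 0 for clusters with ≥ 2 gene models, 1 for single-gene clusters.
Serials follow matrix row order.  Each series holds 999 999 ids;
overflow is an error.  Release diffs classify clusters as unchanged /
split / merged / new / retired by member-set overlap; a 1-to-1 match
with drifted membership keeps the old id and is reported as `unchanged`
(the enum has no "modified" state; the drift is visible in the
matrices).  When naming a new release, the new cluster with the largest
overlap inherits the old id and everything else gets fresh serials.

Note on "singleton": release notes for such catalogs use both "one
genome" and "one gene".  The id scheme follows the one-*gene* reading
(an occupancy-1 cluster holding two paralogs sits in the multi-member
series); the recount helpers for an existing released matrix use the
one-*genome* reading, since released matrices store transcript ids and
gene counts are not recoverable from them.

## Growth curves

`simulate_growth` adds genomes in random order (default **20
permutations**, seeded) and records, for each prefix of g genomes, the
number of clusters present in all g (core) and in ≥ 1 (pan); singleton
clusters are excluded by default.  `fit_growth` fits the core counts of
*all* permutation points by nonlinear least squares
(`scipy.optimize.curve_fit`):

* `tettelin`: n(g) = Ω + κ·exp(−g/τ);
* `willenbrock`: n(g) = Ω + κ₁·exp(−g/τ₁) + κ₂·exp(−g/τ₂).

The two-exponential form is this package's reading of the
Willenbrock-style fit (the original reference describes the weighting
differently; the functional form here is documented and swappable — see
`_willenbrock` in `occupancy.py`).  Initial values Ω₀ = min core count,
κ₀ = range, τ₀ = (#distinct g)/4; 10 restarts with multiplicative jitter
guard against local minima, stopping early once the residual is at
numerical noise.  On real-shaped data the two-exponential tends to sit
a few percent *below* the single-exponential asymptote, which matches
the reported behaviour of the two fits on actual catalogs.

## Evidence by occupancy

Per-gene covariates — AED (annotation edit distance, 0–1, lower =
better transcriptome support), mean expression log₂(FPKM+1), mean pLDDT
(0–100) — are summarised per occupancy value and per class (mean,
median, IQR, n), followed by one-way ANOVA and Tukey HSD across classes;
the core-vs-cloud adjusted p-value is reported separately.  Tukey HSD is
already family-wise, so no further multiple-testing correction is
applied here.  A degenerate table with zero variance reports p = 1
rather than NaN.

## Domain statistics

The representative domain of a pangene is the domain present in the
largest number of member *genomes* (not proteins — chosen for coherence
with the occupancy semantics used everywhere else); ties are broken by a
seeded random draw so releases are reproducible.  Domain-consistency
counts, per genome, the proteins lacking the representative domain.  For
a merged reference genome the counting can be restricted to one source's
models (`genome_filter`) to avoid the merged column inflating counts.

Per-domain profiles: domain occupancy in a pangene = member genomes with
≥ 1 protein carrying it; mean over the pangenes containing the domain;
domains in < 5 pangenes are dropped; categories highly variable (< 10),
partially variable ([10, 15)), invariable (≥ 15) with exactly those
closed/open boundaries.

TE filtering is occupancy-dependent: an occupancy-1 cluster is removed
on *any* TE evidence (TE-classified domain or an annotation flag on the
gene); a cluster of occupancy > 1 only when *every* member gene carries
TE domain evidence.

Enrichment is the hypergeometric upper tail P(X ≥ k) for k foreground
hits among n foreground pangenes drawn from N background with K
term-positives, Benjamini–Hochberg adjusted across terms
(`statsmodels.stats.multitest`), significance at adjusted p < 0.05.

## Peptide support

"Parsimonious" peptide assignment is implemented as greedy minimal set
cover: repeatedly select the protein covering the most unassigned
peptides (ties: larger total peptide count, then lexicographically
smaller id) and give it those peptides.  The greedy choice is the
package's interpretation of the parsimony principle — the principle, not
the algorithm, is what is stated for such resources — and an exhaustive
minimal-cover oracle is provided for testing the classical H(d)
approximation bound.  Peptides shorter than 7 residues are dropped by
default (common proteomics practice; configurable).  Support counts
report proteins with ≥ 2 assigned peptides per genome; the
genome-spread histogram uses the full pre-parsimony mapping.

## Cluster comparison

Each pangene's best match in another clustering is the cluster with the
highest Jaccard index over (normalized) gene-id sets; `overlap/|a|` is
also reported since "percentage of similarity" is ambiguous between the
two.  Summaries count identical matches and matches above configurable
thresholds (default 0.7, i.e. > 70 % similarity) plus median cluster
sizes per side.

## The synthetic-data generator

`synth.generate_pangenome` emulates a 16-genome panel shaped like the
real one — varietal groups japonica 4, aromatic 1, aus 2, indica 9, and
12 chromosomes — with a planted occupancy mix (defaults 500 core, 100
softcore, 200 shell, 150 cloud).  Choices, each fixed once:

* **Layout**: clusters are placed collinearly at shared coordinates
  across genomes; gene lengths uniform in [300, 5000] bp, intergenic
  gaps uniform in [500, 2000] bp (arbitrary but documented; nothing
  downstream depends on them).
* **Rearrangements**: a configurable number of occupancy ≥ 3 clusters is
  translocated (one genome's gene moved to another chromosome) or
  inverted (strand flipped in one genome).  Correspondence edges across
  an inversion keep `same_strand = true`, because the upstream alignment
  is strand-aware; the flag marks alignment strand, not gene strand.
* **Edges**: all cross-genome member pairs, overlap ~ U(0.8, 1.0),
  dropped independently with probability `edge_dropout`; spurious
  cross-strand edges between unrelated genes are added at 1 % of the
  real edge count to exercise the strand-conflict rule.
* **Subfamily bias**: half of the shell/cloud clusters are seeded from a
  single varietal group, so family-segregating pangenes exist in the
  truth; membership is otherwise uniform.
* **Domains**: a fraction (0.6) of multi-member clusters carries a
  cluster-specific domain in every member genome, with a 0.15 chance of
  one genome losing it — the planted domain-consistency outliers;
  separate regime domains with target mean occupancies 15.5 / 12 / 5
  populate the variability categories; TE-flagged cloud genes carry a
  transposase-like marker domain.
* **Evidence**: AED ~ Beta with mean falling linearly from 0.9 at
  occupancy 1 to 0.5 at full occupancy (concentration 10); expression =
  log₂(FPKM+1) with FPKM lognormal and log-mean rising by 2·effect;
  pLDDT normal with mean rising from 55 to 78, sd 8, clipped to
  [0, 100].  These reproduce the reported *trends* (means/medians by
  class) with simple monotone distributions; real catalogs state trends,
  not distributions.
* **Peptides**: `generate_peptides` makes a `shared_fraction` of
  peptides match every protein of one multi-gene cluster and the rest
  unique.

Everything is drawn from one `numpy` Generator seeded by the config, and
file outputs are byte-identical across runs.

What the generator does **not** emulate: nucleotide sequences, alignment
blocks and their errors, annotation-pipeline noise (split/fused gene
models, frame errors), assembly gaps, and realistic chromosome-scale
rearrangement structure.  Passing tests therefore demonstrate the
correctness of the algorithms under clean, known-truth conditions —
exact planted-partition recovery, exact outlier counts, monotone
evidence gradients — not robustness to the gene-model artefacts real
panels contain.

## Problem sizes

The study conditions used by the analysis scripts, the test suite and
`scripts/acceptance.py` are 16 genomes with 950 planted clusters
(~12 000 gene models, ~87 000 edges), 20 growth permutations, and a
3 500-cluster simulated pangenome (planted core 500, accessory presence
probability 0.3 per genome) for asymptote recovery.  These sizes make
every stage's behaviour measurable while each script finishes in
seconds.

## Known limitations

* The Willenbrock-style functional form is a documented stand-in (see
  above); its asymptote on finite panels depends on how well the
  accessory decay matches two exponentials.
* `diff_releases` has no "modified" state (see identifier section).
* The deposited-release recount helpers assume the release's matrix
  dialect (tab-separated, "-" for empty cells, comma-joined transcript
  ids); the cell delimiter of a given release is only verifiable against
  the deposited file itself.
* Chromosome normalization for trans-chromosome detection strips
  genome-specific prefixes and compares trailing integers; unplaced
  scaffolds without a trailing number compare as distinct.
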