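# ricepangenes

Pangene catalogs for panels of annotated rice genome assemblies.

A *pangene* is a cluster of gene models from different genome assemblies
that occupy the same genomic location according to whole-genome alignment
(WGA) — syntenic orthologs, not sequence-similarity orthogroups.  Given a
panel of annotated genomes (such as a 16-cultivar *Oryza sativa*
population reference panel spanning the *japonica*, *aromatic*, *aus* and
*indica* varietal groups), this package

* merges overlapping annotation tracks of a reference genome into a
  non-redundant gene set,
* builds pangene clusters from pairwise WGA gene correspondences,
* assigns versioned stable identifiers of the form
  `Os4530.POR.1.pan0000001`,
* computes the catalog statistics used to characterise such a resource:
  occupancy histograms and core/softcore/shell/cloud classes, core-genome
  growth curves, shared-cluster matrices, subfamily segregation,
  trans-chromosome clusters, protein-domain occupancy and variability,
  peptide-level support, and comparisons against other clusterings,
* and generates synthetic pangenomes with known ground truth so that
  every stage is testable without downloading anything.

## The core definitions

**Clustering.**  Input edges are correspondences `(gene_a, gene_b,
overlap_fraction, same_strand)` produced upstream by WGA plus interval
intersection.  Edges below the overlap threshold (default 0.5) or on
opposite alignment strands are discarded; the rest are united greedily in
descending overlap order into connected components, except that an edge
is vetoed when the union would place two genes that physically overlap on
*opposite strands within one genome* into the same cluster.  Occupancy =
number of genomes with ≥ 1 member; for a panel of N genomes a pangene is
**core** at occupancy N, **softcore** at 95 % of N (15 of 16), **cloud**
at 1–2, and **shell** otherwise.

**Annotation merging.**  Protein-coding genes from different annotation
tracks of one genome are merged when their ranges (same strand) overlap
by ≥ 50 % of the shorter gene's length; merging is transitive, the merged
span is the extreme 5′/3′ extent of the members, and the identifier
follows the source priority RAP-DB > OsNip > MSU.

**Growth curves.**  With genomes added in random order (20 permutation
experiments), the core count is fitted by exponential decay to an
asymptote Ω: the single-exponential `n(g) = Ω + κ·exp(−g/τ)`
(Tettelin-style) or a two-component decay (Willenbrock-style).  Ω is the
estimated core-genome size.

**Domain statistics.**  A pangene's *representative domain* is the domain
carried by the largest number of member genomes; a cluster is
*domain-consistent* when no member genome lacks it.  Per-domain *mean
occupancy* over the pangenes containing the domain classifies domains as
highly variable (< 10), partially variable ([10, 15)) or invariable
(≥ 15) on a 16-genome panel.

## Worked example

The analysis scripts run the whole study on a synthetic 16-genome
pangenome with 500 core / 100 softcore / 200 shell / 150 cloud planted
clusters:

```sh
python analysis/01_simulate_pangenome.py
python analysis/02_build_catalog.py
python analysis/03_occupancy_analysis.py
```

which prints, among other things:

```
clustering: 11955 genes -> 950 pangenes (planted partition recovered exactly: True)
occupancy classes: {'core': 500, 'softcore': 100, 'shell': 200, 'cloud': 150}
tettelin core-size asymptote: 499 genes (tau=5.25)
trans-chromosome pangenes (occupancy>2): 5 (planted translocations with occupancy>2: 5)
aed: core mean 0.501, cloud mean 0.892, core-vs-cloud Tukey p 0
```

Reading: clustering reproduced the planted partition exactly, the class
counts match the planted occupancy mix, the growth fit recovered the
500-cluster core (the asymptote estimate is 499), the five planted
translocations were flagged as trans-chromosome pangenes, and the
generated annotation-quality score (AED, lower = better supported)
degrades from core to cloud clusters with a significant core-vs-cloud
Tukey HSD contrast — the qualitative pattern expected of real panels.
Scripts `04`–`06` continue with domain, peptide-support and
cluster-comparison statistics; derived tables land under `results/`.

The same steps are available as a CLI (`ricepangenes make-fixture`,
`merge`, `cluster`, `assign-ids`, `diff-releases`, `stats`, `domains`,
`peptides`, `compare`, `run`) over the file formats described in
`ricepangenes.io`.

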