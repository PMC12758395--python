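"""Protein-domain statistics over the pangene catalog.

For each pangene the *representative domain* is the domain present in the
largest number of member genomes (ties broken by a seeded random draw so
releases are reproducible).  A multi-member pangene is *domain-consistent*
when no member genome lacks the representative domain.  Per domain, the
*domain occupancy* in a pangene is the number of member genomes carrying
it and the *mean domain occupancy* its mean over all pangenes containing
the domain; domains found in fewer than five pangenes are dropped and the
rest categorised as highly variable (mean < 10), partially variable
([10, 15)) or invariable (>= 15) — thresholds stated for a 16-genome
panel.

TE (transposable-element) filtering is occupancy-dependent: an
occupancy-1 cluster is removed on *any* TE evidence (TE-classified domain
or an annotation flag on its gene); a cluster of occupancy > 1 only when
*every* member gene carries TE domain evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .models import DomainAssignment, Pangene, PangeneMatrix


def _identity(protein_id: str) -> str:
    return protein_id


@dataclass
class DomainProfile:
    domain_acc: str
    namespace: str
    n_pangenes: int
    per_pangene_occupancy: Dict[str, int]
    mean_occupancy: float
    category: str  # highly_variable | partially_variable | invariable


def categorize_occupancy(mean_occupancy: float) -> str:
    if mean_occupancy < 10:
        return "highly_variable"
    if mean_occupancy < 15:
        return "partially_variable"
    return "invariable"


def _genomes_by_domain(
    p: Pangene,
    assignments: Iterable[DomainAssignment],
    namespace: str,
    gene_of: Callable[[str], str],
    genome_filter: Optional[Callable[[str, str], bool]] = None,
) -> Dict[str, Set[str]]:
    """domain_acc -> set of member genomes with >=1 protein carrying it.

    ``genome_filter(genome, gene_id)`` can restrict which member genes
    count (e.g. one-source restriction on a merged reference genome).
    """
    member_of = {
        gene: genome for genome, genes in p.members.items() for gene in genes
    }
    out: Dict[str, Set[str]] = {}
    for a in assignments:
        if a.namespace != namespace:
            continue
        gene = gene_of(a.protein_id)
        genome = member_of.get(gene)
        if genome is None:
            continue
        if genome_filter is not None and not genome_filter(genome, gene):
            continue
        out.setdefault(a.domain_acc, set()).add(genome)
    return out


def representative_domain(
    p: Pangene,
    assignments: Iterable[DomainAssignment],
    namespace: str = "Pfam",
    seed: int = 0,
    gene_of: Callable[[str], str] = _identity,
) -> Tuple[Optional[str], Set[str]]:
    """The most common domain across member genomes, plus the member
    genomes whose proteins all lack it; (None, {}) when no member protein
    carries any domain in the namespace."""
    by_domain = _genomes_by_domain(p, assignments, namespace, gene_of)
    if not by_domain:
        return None, set()
    best = max(len(v) for v in by_domain.values())
    tied = sorted(acc for acc, v in by_domain.items() if len(v) == best)
    if len(tied) == 1:
        rep = tied[0]
    else:
        rep = tied[int(np.random.default_rng(seed).integers(len(tied)))]
    missing = set(p.members) - by_domain[rep]
    return rep, missing


@dataclass
class ConsistencyReport:
    n_annotated: int
    n_consistent: int
    outliers_per_genome: Dict[str, int]
    representative: Dict[str, Optional[str]] = field(default_factory=dict)


def domain_consistency(
    matrix: PangeneMatrix,
    assignments: Sequence[DomainAssignment],
    namespace: str = "Pfam",
    seed: int = 0,
    gene_of: Callable[[str], str] = _identity,
    min_members: int = 2,
) -> ConsistencyReport:
    """Over pangenes with >= min_members gene models: how many carry a
    domain in the namespace, how many are domain-consistent, and per
    genome how many proteins lack the representative domain (outliers)."""
    by_protein: Dict[str, List[DomainAssignment]] = {}
    for a in assignments:
        by_protein.setdefault(gene_of(a.protein_id), []).append(a)
    n_annotated = 0
    n_consistent = 0
    outliers = {g: 0 for g in matrix.panel.genome_ids}
    reps: Dict[str, Optional[str]] = {}
    for i, p in enumerate(matrix.pangenes):
        if p.n_genes < min_members:
            continue
        sub = [a for g in p.gene_ids() for a in by_protein.get(g, [])]
        rep, missing = representative_domain(p, sub, namespace, seed, gene_of)
        key = p.pangene_id if p.pangene_id is not None else str(i)
        reps[key] = rep
        if rep is None:
            continue
        n_annotated += 1
        if not missing:
            n_consistent += 1
            continue
        has_rep = {
            gene_of(a.protein_id)
            for a in sub
            if a.namespace == namespace and a.domain_acc == rep
        }
        for genome, genes in p.members.items():
            if genome in missing:
                outliers[genome] += sum(1 for g in genes if g not in has_rep)
    return ConsistencyReport(
        n_annotated=n_annotated,
        n_consistent=n_consistent,
        outliers_per_genome=outliers,
        representative=reps,
    )


def domain_profiles(
    matrix: PangeneMatrix,
    assignments: Sequence[DomainAssignment],
    namespace: str = "Pfam",
    min_pangenes: int = 5,
    gene_of: Callable[[str], str] = _identity,
    genome_filter: Optional[Callable[[str, str], bool]] = None,
) -> List[DomainProfile]:
    """Occupancy profile per domain across the catalog (filtered to
    domains found in >= min_pangenes pangenes)."""
    by_protein: Dict[str, List[DomainAssignment]] = {}
    for a in assignments:
        by_protein.setdefault(gene_of(a.protein_id), []).append(a)
    per_domain: Dict[str, Dict[str, int]] = {}
    for i, p in enumerate(matrix.pangenes):
        sub = [a for g in p.gene_ids() for a in by_protein.get(g, [])]
        key = p.pangene_id if p.pangene_id is not None else str(i)
        for acc, genomes in _genomes_by_domain(
            p, sub, namespace, gene_of, genome_filter
        ).items():
            per_domain.setdefault(acc, {})[key] = len(genomes)
    out = []
    for acc in sorted(per_domain):
        occ = per_domain[acc]
        if len(occ) < min_pangenes:
            continue
        mean = float(np.mean(list(occ.values())))
        out.append(
            DomainProfile(
                domain_acc=acc,
                namespace=namespace,
                n_pangenes=len(occ),
                per_pangene_occupancy=occ,
                mean_occupancy=mean,
                category=categorize_occupancy(mean),
            )
        )
    return out


def filter_te_clusters(
    matrix: PangeneMatrix,
    assignments: Sequence[DomainAssignment],
    te_flags: Mapping[str, bool] = {},
    gene_of: Callable[[str], str] = _identity,
) -> PangeneMatrix:
    """Drop transposable-element clusters by the occupancy-dependent rule
    (any TE evidence for occupancy-1 clusters; all-members TE domain
    evidence for larger ones)."""
    te_domain_genes: Set[str] = {
        gene_of(a.protein_id) for a in assignments if a.is_te_domain
    }
    kept: List[Pangene] = []
    for p in matrix.pangenes:
        genes = p.gene_ids()
        if p.occupancy == 1:
            if any(g in te_domain_genes or te_flags.get(g, False) for g in genes):
                continue
        else:
            if all(g in te_domain_genes for g in genes):
                continue
        kept.append(Pangene(members=p.members, pangene_id=p.pangene_id))
    return PangeneMatrix(panel=matrix.panel, pangenes=kept)


@dataclass
class EnrichmentResult:
    term: str
    k: int   # foreground hits
    n: int   # foreground size
    K: int   # background hits
    N: int   # background size
    p: float
    p_adj: float
    gene_ratio: float
    significant: bool


def enrich(
    foreground: Set[str],
    background: Set[str],
    term_map: Mapping[str, Set[str]],
    alpha: float = 0.05,
) -> List[EnrichmentResult]:
    """Hypergeometric (upper-tail) term enrichment of a foreground pangene
    set against a background, Benjamini-Hochberg adjusted across terms.

    ``term_map`` maps pangene id -> set of terms (domain accessions, GO
    ids, ...).  P(X >= k) with N background pangenes, K term-positives,
    n foreground draws, k foreground hits.
    """
    if not foreground <= background:
        raise ValueError("foreground must be a subset of background")
    N, n = len(background), len(foreground)
    term_members: Dict[str, Set[str]] = {}
    for pid, terms in term_map.items():
        if pid not in background:
            continue
        for t in terms:
            term_members.setdefault(t, set()).add(pid)
    terms = sorted(term_members)
    pvals = []
    counts = []
    for t in terms:
        members = term_members[t]
        K = len(members)
        k = len(members & foreground)
        p = float(hypergeom.sf(k - 1, N, K, n))
        pvals.append(min(p, 1.0))
        counts.append((k, K))
    if not terms:
        return []
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    out = []
    for t, p, padj, rej, (k, K) in zip(terms, pvals, p_adj, reject, counts):
        out.append(
            EnrichmentResult(
                term=t, k=k, n=n, K=K, N=N, p=p, p_adj=float(padj),
                gene_ratio=(k / n if n else 0.0), significant=bool(rej),
            )
        )
    out.sort(key=lambda r: (r.p_adj, r.p, r.term))
    return out
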