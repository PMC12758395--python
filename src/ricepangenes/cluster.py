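"""Build pangene clusters from pairwise syntenic gene correspondences.

Edges below the overlap threshold or joining genes on opposite alignment
strands are discarded; the surviving edges are united greedily in
descending overlap order into connected components, with a conflict veto:
an edge is skipped when uniting its two components would place two genes
that physically overlap on opposite strands *within one genome* into the
same cluster.  Genes left without edges become singleton pangenes.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Sequence, Tuple

from scipy.cluster.hierarchy import DisjointSet

from .models import (
    Correspondence,
    GeneModel,
    GenomePanel,
    OccClass,
    Pangene,
    PangeneMatrix,
    chrom_number,
)

DEFAULT_MIN_OVERLAP = 0.5


def classify_occupancy(occupancy: int, panel_size: int) -> OccClass:
    """Occupancy class: core = all genomes; softcore = 95% of them
    (15 of 16); cloud = one or two; shell = everything else."""
    if not (1 <= occupancy <= panel_size):
        raise ValueError(
            f"occupancy {occupancy} outside 1..{panel_size}"
        )
    if occupancy == panel_size:
        return OccClass.CORE
    if occupancy <= 2:
        return OccClass.CLOUD
    if occupancy >= math.floor(0.95 * panel_size):
        return OccClass.SOFTCORE
    return OccClass.SHELL


def _strand_conflict(
    genes_a: Dict[str, List[GeneModel]],
    genes_b: Dict[str, List[GeneModel]],
) -> bool:
    """Would merging components with these per-genome genes place two
    physically overlapping opposite-strand genes in one genome together?"""
    for genome in genes_a.keys() & genes_b.keys():
        for ga in genes_a[genome]:
            for gb in genes_b[genome]:
                if ga.strand != gb.strand and ga.overlaps(gb):
                    return True
    return False


def build_clusters(
    genes: Sequence[GeneModel],
    edges: Iterable[Correspondence],
    panel: GenomePanel,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
) -> PangeneMatrix:
    """Cluster genes into pangenes over the correspondence graph.

    Deterministic under edge reordering: edges are processed in descending
    overlap_fraction, ties broken lexicographically by (gene_a, gene_b).
    Multiple genes of one genome may co-cluster (within-genome paralogs).
    """
    if not (0.0 < min_overlap <= 1.0):
        raise ValueError(f"min_overlap {min_overlap} outside (0,1]")
    by_id: Dict[str, GeneModel] = {}
    for g in genes:
        if g.gene_id in by_id:
            raise ValueError(f"duplicate gene id {g.gene_id!r}")
        by_id[g.gene_id] = g

    kept: List[Correspondence] = []
    for e in edges:
        if e.gene_a not in by_id or e.gene_b not in by_id:
            missing = e.gene_a if e.gene_a not in by_id else e.gene_b
            raise ValueError(f"edge references unknown gene {missing!r}")
        if e.overlap_fraction < min_overlap or not e.same_strand:
            continue
        kept.append(e)
    kept.sort(key=lambda e: (-e.overlap_fraction, e.gene_a, e.gene_b))

    ds = DisjointSet(by_id)
    # per-component, per-genome gene lists for the strand-conflict veto
    comp_genes: Dict[str, Dict[str, List[GeneModel]]] = {
        gid: {g.genome: [g]} for gid, g in by_id.items()
    }
    for e in kept:
        ra, rb = ds[e.gene_a], ds[e.gene_b]
        if ra == rb:
            continue
        if _strand_conflict(comp_genes[ra], comp_genes[rb]):
            continue
        ds.merge(e.gene_a, e.gene_b)
        root = ds[e.gene_a]
        bigger, smaller = comp_genes.pop(ra), comp_genes.pop(rb)
        if sum(map(len, smaller.values())) > sum(map(len, bigger.values())):
            bigger, smaller = smaller, bigger
        for genome, lst in smaller.items():
            bigger.setdefault(genome, []).extend(lst)
        comp_genes[root] = bigger

    pangenes: List[Pangene] = []
    for subset in ds.subsets():
        members: Dict[str, List[str]] = {}
        for gid in subset:
            members.setdefault(by_id[gid].genome, []).append(gid)
        for genome in members:
            members[genome].sort(
                key=lambda gid: (by_id[gid].chrom, by_id[gid].start, gid)
            )
        pangenes.append(Pangene(members=members))

    def sort_key(p: Pangene):
        locs = []
        for gid in p.gene_ids():
            g = by_id[gid]
            num = chrom_number(g.chrom)
            locs.append((num if num is not None else 10**6, g.start, gid))
        return min(locs)

    pangenes.sort(key=sort_key)
    return PangeneMatrix(panel=panel, pangenes=pangenes)


def occupancy_classes(matrix: PangeneMatrix) -> List[OccClass]:
    """Occupancy class per matrix row."""
    n = matrix.panel_size
    return [classify_occupancy(p.occupancy, n) for p in matrix.pangenes]
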