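"""Merge several annotation tracks of one genome into a non-redundant gene set.

The japonica reference genome carries three overlapping annotation sources
(RAP-DB, a pipeline-generated OsNip set, and MSU).  Protein-coding genes
are merged when their ranges on the same strand overlap by at least half
of the shorter gene's length; merging is transitive (connected components
of the pairwise overlap graph, evaluated on the original gene ranges), the
merged span is the most extreme 5'/3' extent of the members, and the
merged gene keeps the identifier of its highest-priority member
(RAP-DB > OsNip > MSU by default).

TE-tagged models (an MSU peculiarity) are retained here and only flagged;
occupancy-dependent TE filtering happens downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

from scipy.cluster.hierarchy import DisjointSet

from .models import GeneModel, Source

DEFAULT_PRIORITY: Tuple[Source, ...] = (Source.RAPDB, Source.OSNIP, Source.MSU)

MERGE_THRESHOLD = 0.5


@dataclass
class MergedGene:
    """A connected component of mutually overlapping coding genes."""

    merged_id: str
    members: List[GeneModel]
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def member_ids(self) -> List[str]:
        return [m.gene_id for m in self.members]

    @property
    def sources(self) -> List[Source]:
        return [m.source for m in self.members]

    @property
    def is_te(self) -> bool:
        return all(m.is_te for m in self.members)


def overlap_fraction(a: GeneModel, b: GeneModel) -> float:
    """Overlap of two gene ranges as a fraction of the shorter gene.

    Strand-aware: genes on opposite strands never overlap under this rule.
    Raises when the genes sit on different chromosomes (caller pre-filters).
    """
    if a.chrom != b.chrom:
        raise ValueError(
            f"overlap_fraction: {a.gene_id} and {b.gene_id} on different "
            f"chromosomes ({a.chrom} vs {b.chrom})"
        )
    if a.strand != b.strand:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    if inter <= 0:
        return 0.0
    return inter / min(a.length, b.length)


def merge_annotations(
    tracks: Sequence[Tuple[Source | str, Sequence[GeneModel]]],
    priority: Sequence[Source | str] = DEFAULT_PRIORITY,
    threshold: float = MERGE_THRESHOLD,
) -> List[MergedGene]:
    """Merge annotation tracks of one genome into MergedGene components.

    Non-coding genes are excluded up front.  Pairwise same-strand overlap
    >= ``threshold`` (of the shorter gene, on original ranges) defines
    edges; merged genes are the connected components.  Output is sorted by
    (chrom, start, merged_id) and is idempotent and order-independent.
    """
    priority = [Source(p) for p in priority]
    if not priority:
        raise ValueError("empty source priority list")
    prio_rank = {s: i for i, s in enumerate(priority)}

    genes: List[GeneModel] = []
    seen_ids: Dict[str, Source] = {}
    for source, track in tracks:
        source = Source(source)
        if source not in prio_rank:
            raise ValueError(f"source {source} missing from priority list")
        for g in track:
            if not g.is_coding:
                continue
            if g.gene_id in seen_ids:
                raise ValueError(
                    f"duplicate gene id {g.gene_id!r} across tracks "
                    f"({seen_ids[g.gene_id]} and {source})"
                )
            seen_ids[g.gene_id] = source
            genes.append(g)

    ds = DisjointSet(g.gene_id for g in genes)
    by_key: Dict[Tuple[str, str], List[GeneModel]] = {}
    for g in genes:
        by_key.setdefault((g.chrom, g.strand), []).append(g)
    for group in by_key.values():
        group.sort(key=lambda g: (g.start, g.end, g.gene_id))
        # sweep: compare each gene with later genes until starts pass its end
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                if b.start > a.end:
                    break
                if overlap_fraction(a, b) >= threshold:
                    ds.merge(a.gene_id, b.gene_id)

    by_id = {g.gene_id: g for g in genes}
    merged: List[MergedGene] = []
    for subset in ds.subsets():
        members = sorted(
            (by_id[g] for g in subset),
            key=lambda g: (prio_rank[g.source], g.gene_id),
        )
        head = members[0]
        merged.append(
            MergedGene(
                merged_id=head.gene_id,
                members=members,
                chrom=head.chrom,
                start=min(m.start for m in members),
                end=max(m.end for m in members),
                strand=head.strand,
            )
        )
    merged.sort(key=lambda m: (m.chrom, m.start, m.merged_id))
    return merged


def merged_to_gene_models(merged: Iterable[MergedGene], genome: str) -> List[GeneModel]:
    """Collapse merged components into single GeneModels (one genome column
    for the reference, regardless of how many source tracks fed it)."""
    out = []
    for m in merged:
        transcripts = tuple(t for g in m.members for t in g.transcript_ids)
        out.append(
            GeneModel(
                gene_id=m.merged_id,
                genome=genome,
                source=m.members[0].source,
                chrom=m.chrom,
                start=m.start,
                end=m.end,
                strand=m.strand,
                transcript_ids=transcripts,
                is_coding=True,
                is_te=m.is_te,
            )
        )
    return out


def write_members_tsv(merged: Iterable[MergedGene], path) -> None:
    with open(path, "w") as fh:
        fh.write("merged_id\tmember_ids\tsources\n")
        for m in merged:
            fh.write(
                f"{m.merged_id}\t{','.join(m.member_ids)}\t"
                f"{','.join(s.value for s in m.sources)}\n"
            )
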