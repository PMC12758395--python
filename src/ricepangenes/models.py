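"""Core domain types for pangene catalogs.

A *pangene* is a cluster of gene models from different genome assemblies
that occupy the same genomic location according to whole-genome alignment.
The catalog is a matrix with one row per pangene and one column per input
genome; *occupancy* is the number of genomes contributing at least one
gene model to a row.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple


class Source(str, Enum):
    """Annotation provenance of a gene model.

    RAPDB / OSNIP / MSU are the three overlapping annotation tracks of the
    japonica reference genome; PIPELINE marks models produced by the single
    consistent annotation pipeline used for every other genome in the panel.
    """

    RAPDB = "RAPDB"
    OSNIP = "OSNIP"
    MSU = "MSU"
    PIPELINE = "PIPELINE"


class Subfamily(str, Enum):
    JAPONICA = "japonica"
    AROMATIC = "aromatic"
    AUS = "aus"
    INDICA = "indica"


class OccClass(str, Enum):
    """Occupancy class of a pangene: present in all genomes (core), in 95%
    of them (softcore), in one or two (cloud), anything else (shell)."""

    CORE = "core"
    SOFTCORE = "softcore"
    SHELL = "shell"
    CLOUD = "cloud"


STRANDS = ("+", "-")


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene in one genome (1-based inclusive coordinates)."""

    gene_id: str
    genome: str
    source: Source
    chrom: str
    start: int
    end: int
    strand: str
    transcript_ids: Tuple[str, ...] = ()
    is_coding: bool = True
    is_te: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.is_coding and not self.transcript_ids:
            raise ValueError(
                f"gene {self.gene_id}: coding gene needs >=1 transcript id"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GeneModel") -> bool:
        """Physical interval overlap on the same chromosome (strand-blind)."""
        return self.chrom == other.chrom and not (
            self.end < other.start or other.end < self.start
        )


@dataclass(frozen=True)
class GenomeInfo:
    genome_id: str
    prefix: str
    subfamily: Subfamily


@dataclass(frozen=True)
class GenomePanel:
    """Ordered panel of input genomes (16 for the rice reference panel)."""

    genomes: Tuple[GenomeInfo, ...]

    def __post_init__(self) -> None:
        ids = [g.genome_id for g in self.genomes]
        prefixes = [g.prefix for g in self.genomes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate genome ids in panel")
        if len(set(prefixes)) != len(prefixes):
            raise ValueError("duplicate genome prefixes in panel")
        if len(ids) < 2:
            raise ValueError("panel needs at least 2 genomes")

    def __len__(self) -> int:
        return len(self.genomes)

    def __iter__(self) -> Iterator[GenomeInfo]:
        return iter(self.genomes)

    @property
    def genome_ids(self) -> List[str]:
        return [g.genome_id for g in self.genomes]

    def index(self, genome_id: str) -> int:
        for i, g in enumerate(self.genomes):
            if g.genome_id == genome_id:
                return i
        raise KeyError(genome_id)

    def subfamily_members(self, fam: Subfamily | str) -> List[str]:
        fam = Subfamily(fam)
        return [g.genome_id for g in self.genomes if g.subfamily == fam]


@dataclass(frozen=True)
class Correspondence:
    """Evidence edge between two genes in different genomes, derived from a
    whole-genome-alignment overlap."""

    gene_a: str
    genome_a: str
    gene_b: str
    genome_b: str
    overlap_fraction: float
    same_strand: bool

    def __post_init__(self) -> None:
        if self.genome_a == self.genome_b:
            raise ValueError(
                f"correspondence {self.gene_a}-{self.gene_b}: same genome"
            )
        if not (0.0 < self.overlap_fraction <= 1.0):
            raise ValueError(
                f"correspondence {self.gene_a}-{self.gene_b}: "
                f"overlap_fraction {self.overlap_fraction} outside (0,1]"
            )


@dataclass
class Pangene:
    """One cluster: per-genome member gene lists plus an optional stable id."""

    members: Dict[str, List[str]]
    pangene_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.members = {g: list(v) for g, v in self.members.items() if v}
        if not self.members:
            raise ValueError("pangene with no members")

    @property
    def occupancy(self) -> int:
        return len(self.members)

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.members.values())

    @property
    def is_singleton(self) -> bool:
        """Singleton = cluster containing exactly one gene model."""
        return self.n_genes == 1

    def gene_ids(self) -> List[str]:
        return [g for v in self.members.values() for g in v]

    def gene_set(self) -> frozenset:
        return frozenset(self.gene_ids())

    def genomes(self) -> List[str]:
        return list(self.members)


@dataclass
class PangeneMatrix:
    """The catalog: an ordered list of pangenes over a genome panel."""

    panel: GenomePanel
    pangenes: List[Pangene] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = set(self.panel.genome_ids)
        seen: set = set()
        for p in self.pangenes:
            for genome, genes in p.members.items():
                if genome not in known:
                    raise ValueError(f"unknown genome {genome!r} in pangene")
                for g in genes:
                    if g in seen:
                        raise ValueError(f"gene {g!r} appears in two pangenes")
                    seen.add(g)

    def __len__(self) -> int:
        return len(self.pangenes)

    def __iter__(self) -> Iterator[Pangene]:
        return iter(self.pangenes)

    @property
    def panel_size(self) -> int:
        return len(self.panel)

    def ids(self) -> List[Optional[str]]:
        return [p.pangene_id for p in self.pangenes]

    def gene_to_pangene(self) -> Dict[str, int]:
        """Map gene id -> row index."""
        out: Dict[str, int] = {}
        for i, p in enumerate(self.pangenes):
            for g in p.gene_ids():
                out[g] = i
        return out


@dataclass(frozen=True)
class DomainAssignment:
    """One protein-domain hit on one protein (InterProScan-style)."""

    protein_id: str
    genome: str
    domain_acc: str
    namespace: str  # "Pfam" | "InterPro"
    is_te_domain: bool = False

    def __post_init__(self) -> None:
        if not self.domain_acc:
            raise ValueError("empty domain accession")
        if self.namespace not in ("Pfam", "InterPro"):
            raise ValueError(f"bad namespace {self.namespace!r}")


_CHROM_NUM = re.compile(r"(\d+)\s*$")


def chrom_number(chrom: str) -> Optional[int]:
    """Normalize a chromosome name to its trailing integer (``OsIR64_Chr03``
    -> 3); None when no number can be extracted."""
    m = _CHROM_NUM.search(chrom)
    return int(m.group(1)) if m else None


def make_panel(
    spec: Sequence[Tuple[str, str, str]] | Mapping[str, Tuple[str, str]]
) -> GenomePanel:
    """Build a GenomePanel from (genome_id, prefix, subfamily) triples."""
    if isinstance(spec, Mapping):
        triples = [(gid, pfx, fam) for gid, (pfx, fam) in spec.items()]
    else:
        triples = list(spec)
    return GenomePanel(
        tuple(GenomeInfo(gid, pfx, Subfamily(fam)) for gid, pfx, fam in triples)
    )
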