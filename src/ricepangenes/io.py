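"""Readers and writers for every external table the pipeline touches.

Dialects
--------
* GFF3 gene annotations (1-based inclusive; parsed with gffutils).
* Pangene matrix TSV: column 1 the pangene id, then one column per panel
  genome holding comma-joined member ids, empty cells written as ``-``.
  Read followed by write is byte-identical on well-formed files.
* Correspondence TSV: gene_a, genome_a, gene_b, genome_b,
  overlap_fraction, same_strand.
* InterProScan TSV (standard 11-15 column output).
* Evidence TSV: gene_id, aed, expression, plddt (missing values allowed).
* Peptide map TSV: peptide sequence, semicolon-joined protein ids.

All readers validate ranges and reject rather than coerce bad values.
"""

from __future__ import annotations

import logging
import os
import tempfile
from pathlib import Path
from typing import Callable, Dict, FrozenSet, Iterable, List, Mapping, Optional, Set

import gffutils
import numpy as np
import pandas as pd

from .models import (
    Correspondence,
    DomainAssignment,
    GeneModel,
    GenomePanel,
    Pangene,
    PangeneMatrix,
    Source,
)

log = logging.getLogger(__name__)

EMPTY_CELL = "-"

EVIDENCE_COLUMNS = ["gene_id", "aed", "expression", "plddt"]


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _validate_gff_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}: malformed GFF line {lineno}: "
                    f"expected 9 tab-separated fields, got {len(fields)}"
                )


def read_gff3(
    path: str | os.PathLike,
    genome: str,
    source: Source | str = Source.PIPELINE,
    te_attribute: str = "note",
    te_value: str = "transposable",
) -> List[GeneModel]:
    """Read gene models from a GFF3 file.

    A gene is coding iff at least one child transcript carries a CDS.  A
    gene is flagged as a transposable element when the configurable
    attribute (default key ``note``, matched case-insensitively) contains
    ``te_value`` as a substring.
    """
    path = Path(path)
    source = Source(source)
    _validate_gff_lines(path)
    with open(path) as fh:
        has_features = any(
            line.strip() and not line.startswith("#") for line in fh
        )
    if not has_features:
        return []
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: List[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if feat.strand not in ("+", "-"):
            raise FormatError(
                f"{path}: gene {feat.id}: unknown strand symbol {feat.strand!r}"
            )
        transcripts: List[str] = []
        coding = False
        for child in db.children(feat, level=1):
            if child.featuretype not in ("mRNA", "transcript"):
                continue
            transcripts.append(child.id)
            if any(True for _ in db.children(child, featuretype="CDS")):
                coding = True
        is_te = False
        for key, values in feat.attributes.items():
            if key.lower() != te_attribute.lower():
                continue
            if any(te_value.lower() in v.lower() for v in values):
                is_te = True
        genes.append(
            GeneModel(
                gene_id=feat.id,
                genome=genome,
                source=source,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                transcript_ids=tuple(transcripts),
                is_coding=coding,
                is_te=is_te,
            )
        )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Emit gene/mRNA/CDS features; deterministic ordering by position."""
    genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.is_te:
                attrs += ";note=transposable element"
            fh.write(
                f"{g.chrom}\tricepangenes\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for t in g.transcript_ids:
                fh.write(
                    f"{g.chrom}\tricepangenes\tmRNA\t{g.start}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={t};Parent={g.gene_id}\n"
                )
                if g.is_coding:
                    fh.write(
                        f"{g.chrom}\tricepangenes\tCDS\t{g.start}\t{g.end}\t.\t"
                        f"{g.strand}\t0\tID={t}.cds;Parent={t}\n"
                    )


# ---------------------------------------------------------------------------
# Pangene matrix
# ---------------------------------------------------------------------------

def read_pangene_matrix(
    path: str | os.PathLike,
    panel: GenomePanel,
    empty_token: str = EMPTY_CELL,
) -> PangeneMatrix:
    path = Path(path)
    pangenes: List[Pangene] = []
    seen_ids: Set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 1 + len(panel):
            raise FormatError(
                f"{path}: header has {len(header)} columns, expected "
                f"{1 + len(panel)} (id + {len(panel)} genomes)"
            )
        if header[1:] != panel.genome_ids:
            raise FormatError(
                f"{path}: genome columns {header[1:]} do not match panel "
                f"{panel.genome_ids}"
            )
        for lineno, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != 1 + len(panel):
                raise FormatError(
                    f"{path}: line {lineno}: {len(cells)} columns, expected "
                    f"{1 + len(panel)}"
                )
            pid = cells[0]
            if pid in seen_ids:
                raise FormatError(f"{path}: duplicate pangene id {pid!r}")
            seen_ids.add(pid)
            members = {
                genome: ([] if cell == empty_token else cell.split(","))
                for genome, cell in zip(panel.genome_ids, cells[1:])
            }
            pangenes.append(Pangene(members=members, pangene_id=pid))
    return PangeneMatrix(panel=panel, pangenes=pangenes)


def write_pangene_matrix(
    matrix: PangeneMatrix,
    path: str | os.PathLike,
    empty_token: str = EMPTY_CELL,
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["pangene_id"] + matrix.panel.genome_ids))
        fh.write("\n")
        for p in matrix.pangenes:
            if p.pangene_id is None:
                raise ValueError(
                    "cannot write a matrix with unassigned pangene ids; "
                    "run identifier assignment first"
                )
            cells = [p.pangene_id]
            for genome in matrix.panel.genome_ids:
                genes = p.members.get(genome, [])
                cells.append(",".join(genes) if genes else empty_token)
            fh.write("\t".join(cells))
            fh.write("\n")


# ---------------------------------------------------------------------------
# Correspondences
# ---------------------------------------------------------------------------

_BOOL = {"true": True, "false": False, "1": True, "0": False}


def read_correspondences(path: str | os.PathLike) -> List[Correspondence]:
    """Read WGA-derived gene correspondence edges.

    Rows linking a genome to itself are rejected (counted in the log);
    overlap fractions outside (0, 1] raise.
    """
    path = Path(path)
    edges: List[Correspondence] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "gene_a" and lineno == 1:
                continue
            if len(fields) != 6:
                raise FormatError(
                    f"{path}: line {lineno}: expected 6 columns, got {len(fields)}"
                )
            gene_a, genome_a, gene_b, genome_b, frac_s, strand_s = fields
            if genome_a == genome_b:
                n_rejected += 1
                continue
            try:
                frac = float(frac_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: bad overlap fraction {frac_s!r}"
                ) from exc
            if not (0.0 < frac <= 1.0):
                raise FormatError(
                    f"{path}: line {lineno}: overlap fraction {frac} outside (0,1]"
                )
            try:
                same_strand = _BOOL[strand_s.lower()]
            except KeyError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: bad same_strand {strand_s!r}"
                ) from exc
            edges.append(
                Correspondence(gene_a, genome_a, gene_b, genome_b, frac, same_strand)
            )
    if n_rejected:
        log.warning("%s: rejected %d self-genome correspondence rows", path, n_rejected)
    return edges


def write_correspondences(
    edges: Iterable[Correspondence], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgenome_a\tgene_b\tgenome_b\toverlap_fraction\tsame_strand\n")
        for e in edges:
            fh.write(
                f"{e.gene_a}\t{e.genome_a}\t{e.gene_b}\t{e.genome_b}\t"
                f"{e.overlap_fraction:.6g}\t{'true' if e.same_strand else 'false'}\n"
            )


# ---------------------------------------------------------------------------
# InterProScan
# ---------------------------------------------------------------------------

def read_interproscan(
    path: str | os.PathLike,
    genome_of: Callable[[str], str] | Mapping[str, str],
    te_domains: FrozenSet[str] | Set[str] = frozenset(),
) -> List[DomainAssignment]:
    """Read InterProScan TSV output (one row per signature match).

    Pfam assignments come from the signature accession of ``Pfam`` analysis
    rows; InterPro assignments from the integrated accession column when
    present.  ``genome_of`` attributes each protein to its genome, since
    the format does not carry that information.  Duplicate
    (protein, domain, namespace) records are collapsed.
    """
    if isinstance(genome_of, Mapping):
        mapping = genome_of
        genome_of = lambda p: mapping[p]  # noqa: E731
    path = Path(path)
    seen: Set[tuple] = set()
    out: List[DomainAssignment] = []

    def _add(protein: str, acc: str, namespace: str) -> None:
        key = (protein, acc, namespace)
        if key in seen:
            return
        seen.add(key)
        out.append(
            DomainAssignment(
                protein_id=protein,
                genome=genome_of(protein),
                domain_acc=acc,
                namespace=namespace,
                is_te_domain=acc in te_domains,
            )
        )

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=5 columns, got {len(fields)}"
                )
            protein, analysis, signature = fields[0], fields[3], fields[4]
            if analysis == "Pfam" and signature:
                _add(protein, signature, "Pfam")
            if len(fields) > 11 and fields[11] and fields[11] != "-":
                _add(protein, fields[11], "InterPro")
    return out


def write_interproscan(
    assignments: Iterable[DomainAssignment], path: str | os.PathLike
) -> None:
    """Emit a minimal InterProScan-dialect TSV (12 columns) for round-trips."""
    with open(path, "w") as fh:
        for a in assignments:
            analysis = "Pfam" if a.namespace == "Pfam" else "ProSitePatterns"
            sig = a.domain_acc if a.namespace == "Pfam" else "-"
            ipr = a.domain_acc if a.namespace == "InterPro" else "-"
            fh.write(
                "\t".join(
                    [a.protein_id, "-", "0", analysis, sig, "-", "0", "0",
                     "0.0", "T", "-", ipr]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Evidence table
# ---------------------------------------------------------------------------

def read_evidence(path: str | os.PathLike) -> pd.DataFrame:
    """Per-gene evidence covariates: AED in [0,1], expression (log2(FPKM+1))
    >= 0, mean pLDDT in [0,100]; any field may be missing."""
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""])
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: evidence table lacks columns {sorted(missing)}")
    df = df[EVIDENCE_COLUMNS]
    checks = [
        ("aed", 0.0, 1.0),
        ("expression", 0.0, np.inf),
        ("plddt", 0.0, 100.0),
    ]
    for col, lo, hi in checks:
        vals = df[col].dropna()
        if ((vals < lo) | (vals > hi)).any():
            raise FormatError(f"{path}: column {col} has values outside [{lo},{hi}]")
    return df


def write_evidence(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[EVIDENCE_COLUMNS].to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.6g"
    )


# ---------------------------------------------------------------------------
# Peptide map
# ---------------------------------------------------------------------------

def read_peptide_map(
    path: str | os.PathLike, min_length: int = 7
) -> Dict[str, FrozenSet[str]]:
    """Peptide -> protein-id-set map; peptides shorter than ``min_length``
    residues are dropped (common proteomics practice; configurable)."""
    out: Dict[str, FrozenSet[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "peptide" and lineno == 1:
                continue
            if len(fields) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            pep, prots = fields
            if pep in out:
                raise FormatError(f"{path}: duplicate peptide {pep!r}")
            proteins = frozenset(p for p in prots.split(";") if p)
            if not proteins:
                raise FormatError(f"{path}: line {lineno}: peptide with no proteins")
            if len(pep) < min_length:
                continue
            out[pep] = proteins
    return out


def write_peptide_map(
    pm: Mapping[str, Iterable[str]], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\tproteins\n")
        for pep in sorted(pm):
            fh.write(f"{pep}\t{';'.join(sorted(pm[pep]))}\n")
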