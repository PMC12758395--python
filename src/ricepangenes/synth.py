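"""Synthetic pangenomes with known ground truth.

The generator emulates a 16-genome, 4-subfamily rice panel: a configurable
mix of core / softcore / shell / cloud clusters laid out collinearly on 12
chromosomes, within-genome paralogs, planted inversions and
translocations, TE-flagged genes, per-domain occupancy regimes, and
evidence covariates (AED, expression, pLDDT) whose expectations are
monotone in planted occupancy.  Everything downstream — merging,
clustering, identifiers, statistics — can therefore be tested against
exact planted truth without any downloads.

What it does *not* emulate: nucleotide sequences, alignment blocks,
annotation-pipeline noise beyond the planted structures.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import io as rio
from .models import (
    Correspondence,
    DomainAssignment,
    GeneModel,
    GenomePanel,
    Source,
    Subfamily,
    make_panel,
)

TE_DOMAIN = "PF99901"  # transposase-like marker domain used by the generator

DEFAULT_DOMAIN_REGIMES: Tuple[Tuple[str, float, int], ...] = (
    ("PF10001", 15.5, 30),  # invariable regime
    ("PF10002", 12.0, 30),  # partially variable regime
    ("PF10003", 5.0, 30),   # highly variable regime
)

DEFAULT_SUBFAMILY_SIZES: Dict[str, int] = {
    "japonica": 4,
    "aromatic": 1,
    "aus": 2,
    "indica": 9,
}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic pangenome.

    Defaults mirror the real panel's shape (16 genomes split 4 japonica /
    1 aromatic / 2 aus / 9 indica over 12 chromosomes) at a desk-scale
    cluster count (500 core, 100 softcore, 200 shell, 150 cloud).
    """

    n_genomes: int = 16
    subfamily_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBFAMILY_SIZES)
    )
    n_core: int = 500
    n_softcore: int = 100
    n_shell: int = 200
    n_cloud: int = 150
    paralog_rate: float = 0.05
    te_fraction: float = 0.05
    n_chromosomes: int = 12
    planted_translocations: int = 5
    planted_inversions: int = 2
    domain_regimes: Tuple[Tuple[str, float, int], ...] = DEFAULT_DOMAIN_REGIMES
    evidence_effect: float = 1.0
    edge_dropout: float = 0.0
    spurious_edge_fraction: float = 0.01
    # fraction of shell/cloud clusters whose membership is drawn from one
    # varietal group first (creates family-segregating pangenes)
    subfamily_bias: float = 0.5
    # fraction of multi-member clusters carrying a cluster-specific domain
    # in every member genome, and how often one genome loses it (planted
    # domain-consistency outliers)
    consistent_domain_fraction: float = 0.6
    domain_outlier_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.subfamily_sizes.values()) != self.n_genomes:
            raise ConfigError(
                f"subfamily sizes sum to {sum(self.subfamily_sizes.values())}, "
                f"expected n_genomes={self.n_genomes}"
            )
        for name in ("n_core", "n_softcore", "n_shell", "n_cloud"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_shell > 0 and self.n_genomes < 5:
            raise ConfigError("shell clusters need a panel of >= 5 genomes")
        if self.n_softcore > 0 and self.n_genomes < 3:
            raise ConfigError("softcore clusters need a panel of >= 3 genomes")
        for name in ("paralog_rate", "te_fraction", "edge_dropout",
                     "spurious_edge_fraction", "subfamily_bias",
                     "consistent_domain_fraction", "domain_outlier_rate"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ConfigError(f"{name} must be in [0,1)")
        if self.evidence_effect < 0:
            raise ConfigError("evidence_effect must be >= 0")
        if self.n_chromosomes < 1:
            raise ConfigError("need >= 1 chromosome")

    @property
    def n_clusters(self) -> int:
        return self.n_core + self.n_softcore + self.n_shell + self.n_cloud


@dataclass
class SynthTruth:
    planted_clusters: Dict[str, Dict[str, List[str]]]
    planted_occupancy: Dict[str, int]
    planted_domain_occupancy: Dict[Tuple[str, str], int]
    translocated_clusters: Set[str]
    inverted_clusters: Set[str]
    te_genes: Set[str]
    # cluster-specific domains planted in every member genome, and the
    # genomes from which the domain was deliberately dropped
    consistent_domain_of: Dict[str, str] = field(default_factory=dict)
    domain_outlier_genomes: Dict[str, Set[str]] = field(default_factory=dict)
    # member genomes actually carrying each occupancy-regime domain
    regime_carriers: Dict[Tuple[str, str], Set[str]] = field(default_factory=dict)

    def cluster_sets(self) -> Set[FrozenSet[str]]:
        return {
            frozenset(g for genes in members.values() for g in genes)
            for members in self.planted_clusters.values()
        }


@dataclass
class SyntheticPangenome:
    config: SynthConfig
    panel: GenomePanel
    genes: Dict[str, List[GeneModel]]          # genome -> gene models
    correspondences: List[Correspondence]
    domain_assignments: List[DomainAssignment]
    evidence: pd.DataFrame
    truth: SynthTruth
    paths: Dict[str, Path] = field(default_factory=dict)

    def all_genes(self) -> List[GeneModel]:
        return [g for lst in self.genes.values() for g in lst]


def default_panel(subfamily_sizes: Mapping[str, int]) -> GenomePanel:
    triples = []
    tag = {"japonica": "Jap", "aromatic": "Aro", "aus": "Aus", "indica": "Ind"}
    for fam in ("japonica", "aromatic", "aus", "indica"):
        for i in range(subfamily_sizes.get(fam, 0)):
            gid = f"Os{tag[fam]}{i + 1:02d}"
            triples.append((gid, f"{gid}_", fam))
    return make_panel(triples)


def _draw_occupancies(cfg: SynthConfig, rng: np.random.Generator) -> List[int]:
    n = cfg.n_genomes
    occ: List[int] = []
    occ += [n] * cfg.n_core
    occ += [n - 1] * cfg.n_softcore
    if cfg.n_shell:
        occ += list(rng.integers(3, n - 1, size=cfg.n_shell))  # 3..n-2
    if cfg.n_cloud:
        occ += list(rng.integers(1, 3, size=cfg.n_cloud))      # 1..2
    return occ


def _draw_members(
    cfg: SynthConfig,
    panel: GenomePanel,
    occ: int,
    rng: np.random.Generator,
) -> List[str]:
    """Member genomes for one cluster.  Shell/cloud clusters are, with
    probability ``subfamily_bias``, seeded from a single varietal group
    (filled from that group first) so family-segregating pangenes exist."""
    genome_ids = panel.genome_ids
    n = len(genome_ids)
    if 1 <= occ <= n - 2 and rng.random() < cfg.subfamily_bias:
        fams = sorted({g.subfamily for g in panel}, key=lambda f: f.value)
        weights = np.array(
            [len(panel.subfamily_members(f)) for f in fams], dtype=float
        )
        fam = fams[int(rng.choice(len(fams), p=weights / weights.sum()))]
        inside = list(panel.subfamily_members(fam))
        outside = [g for g in genome_ids if g not in inside]
        picked = list(rng.permutation(inside)[:occ])
        if len(picked) < occ:
            picked += list(rng.permutation(outside)[: occ - len(picked)])
        return sorted(str(g) for g in picked)
    return sorted(str(g) for g in rng.choice(genome_ids, size=occ, replace=False))


def generate_pangenome(
    cfg: SynthConfig, outdir: Optional[Path | str] = None
) -> SyntheticPangenome:
    """Generate one synthetic pangenome; fully reproducible from cfg.seed.

    When ``outdir`` is given, per-genome GFF3 files, the correspondence
    table, the domain table and the evidence table are also written there
    (byte-identical across runs with the same config).
    """
    rng = np.random.default_rng(cfg.seed)
    panel = default_panel(cfg.subfamily_sizes)
    genome_ids = panel.genome_ids
    prefix = {g.genome_id: g.prefix for g in panel}

    occupancies = _draw_occupancies(cfg, rng)
    order = rng.permutation(len(occupancies))  # interleave classes positionally
    cluster_ids = [f"truth{int(i):05d}" for i in range(len(occupancies))]

    # collinear layout: shared coordinates across genomes
    per_chrom = -(-len(occupancies) // cfg.n_chromosomes)
    cursors = {c: 1 for c in range(1, cfg.n_chromosomes + 1)}
    placements: List[Tuple[str, int, int, int]] = []  # cid, chrom, start, end
    members_of: Dict[str, List[str]] = {}
    for slot, idx in enumerate(order):
        cid = cluster_ids[idx]
        occ = occupancies[idx]
        chrom = (slot // per_chrom) + 1
        length = int(rng.integers(300, 5001))
        gap = int(rng.integers(500, 2001))
        start = cursors[chrom]
        cursors[chrom] = start + length + gap
        placements.append((cid, chrom, start, start + length - 1))
        members_of[cid] = _draw_members(cfg, panel, occ, rng)

    # planted rearrangements
    eligible = [cid for cid in members_of if len(members_of[cid]) >= 3]
    rng.shuffle(eligible)
    if cfg.planted_translocations > len(eligible):
        raise ConfigError("not enough occupancy>=3 clusters for translocations")
    translocated = set(eligible[: cfg.planted_translocations])
    inverted = set(
        eligible[cfg.planted_translocations:
                 cfg.planted_translocations + cfg.planted_inversions]
    )
    trans_genome = {cid: members_of[cid][int(rng.integers(len(members_of[cid])))]
                    for cid in sorted(translocated)}
    inv_genome = {cid: members_of[cid][int(rng.integers(len(members_of[cid])))]
                  for cid in sorted(inverted)}

    genes: Dict[str, List[GeneModel]] = {g: [] for g in genome_ids}
    planted: Dict[str, Dict[str, List[str]]] = {}
    te_genes: Set[str] = set()
    gene_occ: Dict[str, int] = {}
    gene_cluster: Dict[str, str] = {}
    for cid, chrom, start, end in placements:
        members = members_of[cid]
        occ = len(members)
        cluster_is_te = occ <= 2 and rng.random() < cfg.te_fraction
        planted[cid] = {}
        for genome in members:
            gid = f"{prefix[genome]}g{cid[5:]}"
            g_chrom = chrom
            g_start, g_end = start, end
            if cid in translocated and genome == trans_genome[cid]:
                g_chrom = (chrom + cfg.n_chromosomes // 2 - 1) % cfg.n_chromosomes + 1
                g_start, g_end = start + 30_000_000, end + 30_000_000
            strand = "-" if (cid in inverted and genome == inv_genome[cid]) else "+"
            copies = [gid]
            # paralogs only in multi-genome clusters: a lone within-genome
            # duplicate has no cross-genome alignment edge tying it back
            if occ >= 2 and rng.random() < cfg.paralog_rate:
                copies.append(gid + "b")
            cluster_genes = []
            for j, copy_id in enumerate(copies):
                offset = j * ((g_end - g_start + 1) + 200)
                genes[genome].append(
                    GeneModel(
                        gene_id=copy_id,
                        genome=genome,
                        source=Source.PIPELINE,
                        chrom=f"{genome}_Chr{g_chrom:02d}",
                        start=g_start + offset,
                        end=g_end + offset,
                        strand=strand,
                        transcript_ids=(copy_id + ".t1",),
                        is_coding=True,
                        is_te=cluster_is_te,
                    )
                )
                cluster_genes.append(copy_id)
                gene_occ[copy_id] = occ
                gene_cluster[copy_id] = cid
                if cluster_is_te:
                    te_genes.add(copy_id)
            planted[cid][genome] = cluster_genes

    # correspondence edges: all cross-genome pairs within a cluster
    edges: List[Correspondence] = []
    for cid in cluster_ids:
        flat = [(genome, g) for genome in planted[cid] for g in planted[cid][genome]]
        for i in range(len(flat)):
            for j in range(i + 1, len(flat)):
                (ga_gen, ga), (gb_gen, gb) = flat[i], flat[j]
                if ga_gen == gb_gen:
                    continue
                if rng.random() < cfg.edge_dropout:
                    continue
                edges.append(
                    Correspondence(
                        gene_a=ga, genome_a=ga_gen,
                        gene_b=gb, genome_b=gb_gen,
                        overlap_fraction=float(rng.uniform(0.8, 1.0)),
                        same_strand=True,
                    )
                )
    # spurious cross-strand edges between unrelated genes (these exercise
    # the strand-conflict rule and must never merge clusters)
    n_spurious = int(round(cfg.spurious_edge_fraction * len(edges)))
    all_flat = [(genome, g.gene_id) for genome in genome_ids for g in genes[genome]]
    attempts = 0
    made = 0
    while made < n_spurious and attempts < 50 * max(n_spurious, 1):
        attempts += 1
        i, j = rng.integers(len(all_flat), size=2)
        (ga_gen, ga), (gb_gen, gb) = all_flat[int(i)], all_flat[int(j)]
        if ga_gen == gb_gen or gene_cluster[ga] == gene_cluster[gb]:
            continue
        edges.append(
            Correspondence(
                gene_a=ga, genome_a=ga_gen, gene_b=gb, genome_b=gb_gen,
                overlap_fraction=float(rng.uniform(0.5, 0.7)),
                same_strand=False,
            )
        )
        made += 1

    # domain regimes
    assignments: List[DomainAssignment] = []
    domain_occ: Dict[Tuple[str, str], int] = {}
    for gid in sorted(te_genes):
        genome = next(g for g in genome_ids if gid.startswith(prefix[g]))
        assignments.append(
            DomainAssignment(gid, genome, TE_DOMAIN, "Pfam", is_te_domain=True)
        )
    # cluster-specific domains: planted in every member genome of a
    # fraction of multi-member clusters, with occasional single-genome
    # dropouts (the planted domain-consistency outliers)
    consistent_domain_of: Dict[str, str] = {}
    domain_outlier_genomes: Dict[str, Set[str]] = {}
    for k, cid in enumerate(cluster_ids):
        members = members_of[cid]
        n_cluster_genes = sum(len(planted[cid][g]) for g in members)
        if n_cluster_genes < 2:
            continue
        if any(g in te_genes for genes_ in planted[cid].values() for g in genes_):
            continue  # TE marker domain would compete for representative
        if rng.random() >= cfg.consistent_domain_fraction:
            continue
        acc = f"PF2{k:04d}"
        carriers = list(members)
        outliers: Set[str] = set()
        if len(members) > 1 and rng.random() < cfg.domain_outlier_rate:
            dropped = members[int(rng.integers(len(members)))]
            carriers = [g for g in members if g != dropped]
            outliers = {dropped}
        consistent_domain_of[cid] = acc
        domain_outlier_genomes[cid] = outliers
        for genome in carriers:
            for gid in planted[cid][genome]:
                assignments.append(
                    DomainAssignment(gid, genome, acc, "Pfam", False)
                )

    regime_carriers: Dict[Tuple[str, str], Set[str]] = {}
    used_by_regime: Set[str] = set()
    for acc, target_mean, n_pg in cfg.domain_regimes:
        candidates = [cid for cid in cluster_ids
                      if cid not in consistent_domain_of
                      and cid not in used_by_regime
                      and len(members_of[cid]) >= min(cfg.n_genomes, round(target_mean))]
        if len(candidates) < n_pg:
            candidates = sorted(
                (c for c in cluster_ids
                 if c not in consistent_domain_of and c not in used_by_regime),
                key=lambda c: -len(members_of[c]),
            )[: max(n_pg, 1)]
        chosen = rng.choice(len(candidates), size=min(n_pg, len(candidates)),
                            replace=False)
        for ci in sorted(int(c) for c in chosen):
            cid = candidates[ci]
            used_by_regime.add(cid)
            occ = len(members_of[cid])
            t = int(np.clip(round(rng.normal(target_mean, 1.0)), 1, occ))
            carriers = sorted(rng.choice(members_of[cid], size=t, replace=False))
            domain_occ[(acc, cid)] = t
            regime_carriers[(acc, cid)] = set(carriers)
            for genome in carriers:
                for gid in planted[cid][genome]:
                    assignments.append(
                        DomainAssignment(gid, genome, acc, "Pfam", False)
                    )

    # evidence covariates, monotone in planted occupancy
    n = cfg.n_genomes
    rows = []
    eff = cfg.evidence_effect
    for genome in genome_ids:
        for g in genes[genome]:
            occ = gene_occ[g.gene_id]
            frac = (occ - 1) / max(n - 1, 1)
            mu_aed = float(np.clip(0.9 - 0.4 * eff * frac, 0.05, 0.95))
            aed = float(rng.beta(mu_aed * 10, (1 - mu_aed) * 10))
            fpkm = float(rng.lognormal(mean=np.log(2.0) + 2.0 * eff * frac,
                                       sigma=0.8))
            expression = float(np.log2(fpkm + 1.0))
            plddt = float(np.clip(rng.normal(55 + 23 * eff * frac, 8.0), 0, 100))
            rows.append((g.gene_id, aed, expression, plddt))
    evidence = pd.DataFrame(rows, columns=rio.EVIDENCE_COLUMNS)

    truth = SynthTruth(
        planted_clusters=planted,
        planted_occupancy={cid: len(m) for cid, m in members_of.items()},
        planted_domain_occupancy=domain_occ,
        translocated_clusters=translocated,
        inverted_clusters=inverted,
        te_genes=te_genes,
        consistent_domain_of=consistent_domain_of,
        domain_outlier_genomes=domain_outlier_genomes,
        regime_carriers=regime_carriers,
    )
    out = SyntheticPangenome(
        config=cfg, panel=panel, genes=genes, correspondences=edges,
        domain_assignments=assignments, evidence=evidence, truth=truth,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for genome in genome_ids:
            p = outdir / f"{genome}.gff3"
            rio.write_gff3(genes[genome], p)
            out.paths[genome] = p
        out.paths["edges"] = outdir / "edges.tsv"
        rio.write_correspondences(edges, out.paths["edges"])
        out.paths["domains"] = outdir / "domains.tsv"
        rio.write_interproscan(assignments, out.paths["domains"])
        out.paths["evidence"] = outdir / "evidence.tsv"
        rio.write_evidence(evidence, out.paths["evidence"])
    return out


# ---------------------------------------------------------------------------
# reference-genome annotation tracks (three overlapping sources)
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTracks:
    tracks: Dict[Source, List[GeneModel]]
    merge_truth: List[FrozenSet[str]]   # coding genes that must merge together
    paths: Dict[Source, Path] = field(default_factory=dict)


def generate_reference_tracks(
    cfg: SynthConfig, outdir: Optional[Path | str] = None, n_loci: int = 40
) -> ReferenceTracks:
    """Three overlapping annotation tracks for the panel's first genome.

    Planted structure: three-source loci that must merge; boundary pairs
    with overlap fractions 0.49 (must stay separate) and 0.51 (must
    merge); per-source singletons; TE-flagged MSU-only genes; one
    non-coding gene that merging must ignore.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    panel = default_panel(cfg.subfamily_sizes)
    genome = panel.genome_ids[0]
    chrom = f"{genome}_Chr01"
    tracks: Dict[Source, List[GeneModel]] = {
        Source.RAPDB: [], Source.OSNIP: [], Source.MSU: []
    }
    merge_truth: List[FrozenSet[str]] = []
    cursor = 1
    counter = {s: 0 for s in tracks}

    def add(source: Source, start: int, end: int, strand: str = "+",
            coding: bool = True, te: bool = False) -> str:
        counter[source] += 1
        gid = f"{source.value}_{counter[source]:04d}"
        tracks[source].append(
            GeneModel(
                gene_id=gid, genome=genome, source=source, chrom=chrom,
                start=start, end=end, strand=strand,
                transcript_ids=(gid + ".t1",) if coding else (),
                is_coding=coding, is_te=te,
            )
        )
        return gid

    for locus in range(n_loci):
        kind = locus % 8
        L = int(rng.integers(600, 2400))
        start = cursor
        end = start + L - 1
        if kind == 0:  # all three sources, heavy mutual overlap -> one gene
            ids = [
                add(Source.RAPDB, start, end),
                add(Source.OSNIP, start + L // 10, end + L // 10),
                add(Source.MSU, start - L // 10, end - L // 10),
            ]
            merge_truth.append(frozenset(ids))
        elif kind == 1:  # boundary pair at 0.49: must NOT merge
            L = 100
            end = start + L - 1
            a = add(Source.RAPDB, start, end)
            b = add(Source.OSNIP, start + 51, end + 51)
            merge_truth.append(frozenset([a]))
            merge_truth.append(frozenset([b]))
            end = end + 51
        elif kind == 2:  # boundary pair at 0.51: must merge
            L = 100
            end = start + L - 1
            a = add(Source.RAPDB, start, end)
            b = add(Source.OSNIP, start + 49, end + 49)
            merge_truth.append(frozenset([a, b]))
            end = end + 49
        elif kind == 3:  # RAPDB + OSNIP pair, ~0.7 overlap
            a = add(Source.RAPDB, start, end)
            b = add(Source.OSNIP, start + int(0.3 * L), end + int(0.3 * L))
            merge_truth.append(frozenset([a, b]))
            end = end + int(0.3 * L)
        elif kind == 4:  # per-source singleton
            src = (Source.RAPDB, Source.OSNIP, Source.MSU)[locus % 3]
            merge_truth.append(frozenset([add(src, start, end)]))
        elif kind == 5:  # MSU-only gene, possibly TE-flagged
            te = cfg.te_fraction > 0 and rng.random() < max(cfg.te_fraction, 0.5)
            merge_truth.append(frozenset([add(Source.MSU, start, end, te=te)]))
        elif kind == 6:  # antisense overlap: same span, opposite strand
            a = add(Source.RAPDB, start, end, strand="+")
            b = add(Source.OSNIP, start, end, strand="-")
            merge_truth.append(frozenset([a]))
            merge_truth.append(frozenset([b]))
        else:  # non-coding OSNIP gene over a coding RAPDB gene: ignored
            a = add(Source.RAPDB, start, end)
            add(Source.OSNIP, start, end, coding=False)
            merge_truth.append(frozenset([a]))
        cursor = end + int(rng.integers(500, 2001))

    out = ReferenceTracks(tracks=tracks, merge_truth=merge_truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for source, genes_ in tracks.items():
            p = outdir / f"{genome}.{source.value}.gff3"
            rio.write_gff3(genes_, p)
            out.paths[source] = p
    return out


# ---------------------------------------------------------------------------
# peptides
# ---------------------------------------------------------------------------

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def generate_peptides(
    truth: SynthTruth,
    n_peptides: int,
    shared_fraction: float,
    seed: int = 0,
) -> Tuple[Dict[str, FrozenSet[str]], Set[str]]:
    """Peptide -> protein-set map over the truth's genes.

    ``shared_fraction`` of peptides map to every protein of one
    multi-genome cluster (within-cluster sharing across genomes); the rest
    are unique to one protein.  Returns (map, minimal covering protein
    set computed from construction).
    """
    if n_peptides < 1:
        raise ValueError("n_peptides must be >= 1")
    if not (0.0 <= shared_fraction <= 1.0):
        raise ValueError("shared_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    clusters = sorted(truth.planted_clusters)
    multi = [c for c in clusters
             if sum(len(v) for v in truth.planted_clusters[c].values()) >= 2]
    pm: Dict[str, FrozenSet[str]] = {}
    cover: Set[str] = set()
    n_shared = int(round(shared_fraction * n_peptides))
    while len(pm) < n_peptides:
        seq = "".join(rng.choice(AA, size=int(rng.integers(9, 21))))
        if seq in pm:
            continue
        if len(pm) < n_shared and multi:
            cid = multi[int(rng.integers(len(multi)))]
            prots = frozenset(
                g for genes in truth.planted_clusters[cid].values() for g in genes
            )
            # any single member protein can explain the peptide; construction
            # minimal cover takes the lexicographically smallest
            cover.add(min(prots))
        else:
            cid = clusters[int(rng.integers(len(clusters)))]
            genes = [g for v in truth.planted_clusters[cid].values() for g in v]
            prots = frozenset([genes[int(rng.integers(len(genes)))]])
            cover.add(next(iter(prots)))
        pm[seq] = prots
    return pm, cover
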