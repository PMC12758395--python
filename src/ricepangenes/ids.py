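"""Stable pangene identifiers and release-to-release mappings.

The identifier scheme is ``[clade].[group].[version].panDDDDDDD`` — e.g.
``Os4530.POR.1.pan0020022`` — where *clade* is a one- or two-letter code
followed by the NCBI taxon id, *group* a three-letter consortium code,
*version* a positive release integer, and the seven digits split into a
series digit (0 for clusters with two or more gene models, 1 for
singleton clusters holding a single gene) plus a six-digit serial.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Dict, FrozenSet, List, Optional, Tuple

from .models import Pangene, PangeneMatrix

_ID_RE = re.compile(
    r"^(?P<clade>[A-Za-z]{1,2}\d+)\.(?P<group>[A-Z]{3})\.(?P<version>\d+)"
    r"\.pan(?P<series>[01])(?P<serial>\d{6})$"
)

SERIAL_CAPACITY = 999_999


@dataclass(frozen=True)
class IdScheme:
    clade: str = "Os4530"
    group: str = "POR"
    version: int = 1

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[A-Za-z]{1,2}\d+", self.clade):
            raise ValueError(f"bad clade code {self.clade!r}")
        if not re.fullmatch(r"[A-Z]{3}", self.group):
            raise ValueError(f"group must match [A-Z]{{3}}, got {self.group!r}")
        if self.version < 1:
            raise ValueError("version must be >= 1")

    def format(self, serial: int, singleton: bool) -> str:
        if not (1 <= serial <= SERIAL_CAPACITY):
            raise ValueError(
                f"serial {serial} outside 1..{SERIAL_CAPACITY} "
                f"({'singleton' if singleton else 'multi-member'} series full)"
            )
        series = 1 if singleton else 0
        return f"{self.clade}.{self.group}.{self.version}.pan{series}{serial:06d}"


def parse_id(pangene_id: str) -> Tuple[IdScheme, int, bool]:
    """Parse a stable id into (scheme, serial, is_singleton_series);
    the left inverse of :meth:`IdScheme.format`."""
    m = _ID_RE.match(pangene_id)
    if not m:
        raise ValueError(f"unparseable pangene id {pangene_id!r}")
    scheme = IdScheme(m["clade"], m["group"], int(m["version"]))
    return scheme, int(m["serial"]), m["series"] == "1"


def assign_ids(matrix: PangeneMatrix, scheme: IdScheme = IdScheme()) -> PangeneMatrix:
    """Assign fresh stable ids in matrix row order: multi-member clusters
    take the pan0000001... series, singletons pan1000001...; returns a new
    matrix, leaving the input untouched."""
    if any(p.pangene_id is not None for p in matrix.pangenes):
        raise ValueError("matrix already carries pangene ids")
    out: List[Pangene] = []
    next_serial = {False: 1, True: 1}
    for p in matrix.pangenes:
        singleton = p.is_singleton
        pid = scheme.format(next_serial[singleton], singleton)
        next_serial[singleton] += 1
        out.append(Pangene(members=p.members, pangene_id=pid))
    return PangeneMatrix(panel=matrix.panel, pangenes=out)


@dataclass(frozen=True)
class IdMappingRow:
    old_id: str
    new_id: str
    reason: str  # unchanged | split | merged | new | retired


def diff_releases(old: PangeneMatrix, new: PangeneMatrix) -> List[IdMappingRow]:
    """Track how clusters changed between releases over a shared gene-id
    namespace.

    Identical member sets carry the old id forward (``unchanged``); an old
    cluster whose genes land in several new clusters yields one ``split``
    row per new cluster; several old clusters landing in one new cluster
    yield ``merged`` rows; new clusters of previously unclustered genes
    are ``new``; old clusters with no overlap at all are ``retired``.
    """
    for matrix, name in ((old, "old"), (new, "new")):
        ids = [p.pangene_id for p in matrix.pangenes]
        if None in ids:
            raise ValueError(f"{name} release has unassigned pangene ids")
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate pangene ids within {name} release")

    old_sets = {p.pangene_id: p.gene_set() for p in old.pangenes}
    new_sets = {p.pangene_id: p.gene_set() for p in new.pangenes}
    gene_to_new: Dict[str, str] = {
        g: pid for pid, s in new_sets.items() for g in s
    }
    gene_to_old: Dict[str, str] = {
        g: pid for pid, s in old_sets.items() for g in s
    }

    # overlap[old_id] = {new_id: shared gene count}
    overlap: Dict[str, Dict[str, int]] = {}
    for oid, s in old_sets.items():
        counts: Dict[str, int] = {}
        for g in s:
            nid = gene_to_new.get(g)
            if nid is not None:
                counts[nid] = counts.get(nid, 0) + 1
        overlap[oid] = counts
    rev_overlap: Dict[str, List[str]] = {}
    for oid, counts in overlap.items():
        for nid in counts:
            rev_overlap.setdefault(nid, []).append(oid)

    rows: List[IdMappingRow] = []
    for oid in old_sets:
        counts = overlap[oid]
        if not counts:
            rows.append(IdMappingRow(oid, "", "retired"))
            continue
        new_ids = sorted(counts)
        for nid in new_ids:
            if new_sets[nid] == old_sets[oid]:
                reason = "unchanged"
            elif len(counts) > 1:
                reason = "split"
            elif len(rev_overlap[nid]) > 1:
                reason = "merged"
            else:
                # 1-to-1 with drifted membership: id carried forward
                reason = "unchanged"
            rows.append(IdMappingRow(oid, nid, reason))
    for nid, s in new_sets.items():
        if all(g not in gene_to_old for g in s):
            rows.append(IdMappingRow("", nid, "new"))
    return rows


def carry_forward_ids(
    old: PangeneMatrix, new_unnamed: PangeneMatrix, scheme: IdScheme
) -> PangeneMatrix:
    """Name a new release: a cluster identical (or largest-overlap) to an
    old one inherits its id; everything else gets a fresh serial after the
    old release's highest serials."""
    old_by_set: Dict[FrozenSet[str], str] = {
        p.gene_set(): p.pangene_id for p in old.pangenes
    }
    gene_to_old_id = {g: p.pangene_id for p in old.pangenes for g in p.gene_ids()}
    max_serial = {False: 0, True: 0}
    for p in old.pangenes:
        _, serial, singleton = parse_id(p.pangene_id)
        max_serial[singleton] = max(max_serial[singleton], serial)

    # best new cluster per old id (largest gene overlap) inherits the id
    best_claim: Dict[str, Tuple[int, int]] = {}  # old_id -> (overlap, row)
    for i, p in enumerate(new_unnamed.pangenes):
        counts: Dict[str, int] = {}
        for g in p.gene_ids():
            oid = gene_to_old_id.get(g)
            if oid:
                counts[oid] = counts.get(oid, 0) + 1
        for oid, c in counts.items():
            if oid not in best_claim or c > best_claim[oid][0]:
                best_claim[oid] = (c, i)
    inherit: Dict[int, str] = {}
    for oid, (_, row) in best_claim.items():
        if row not in inherit:
            inherit[row] = oid

    out: List[Pangene] = []
    next_serial = {k: v + 1 for k, v in max_serial.items()}
    for i, p in enumerate(new_unnamed.pangenes):
        exact = old_by_set.get(p.gene_set())
        pid = exact if exact is not None else inherit.get(i)
        if pid is None:
            singleton = p.is_singleton
            pid = scheme.format(next_serial[singleton], singleton)
            next_serial[singleton] += 1
        out.append(Pangene(members=p.members, pangene_id=pid))
    ids = [p.pangene_id for p in out]
    if len(set(ids)) != len(ids):
        raise ValueError("carry-forward produced duplicate ids")
    return PangeneMatrix(panel=new_unnamed.panel, pangenes=out)


def write_id_mapping(rows: List[IdMappingRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("old_id\tnew_id\treason\n")
        for r in rows:
            fh.write(f"{r.old_id}\t{r.new_id}\t{r.reason}\n")
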