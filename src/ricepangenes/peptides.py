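"""Peptide-level support for the pangene catalog.

Shotgun proteomics yields peptides that often match several gene products
(paralogs within a genome, orthologs across genomes).  Support counting
uses a *parsimonious* assignment: each peptide is given to exactly one
protein, chosen by a greedy minimal set cover (the protein explaining the
most still-unassigned peptides is selected repeatedly; ties go to the
protein with more total mapped peptides, then to the lexicographically
smaller id — fully deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Set, Tuple


@dataclass
class ParsimonyAssignment:
    assignment: Dict[str, str]        # peptide -> the one protein it keeps
    selected_proteins: List[str]      # cover, in selection order


def parsimonious_assign(pm: Mapping[str, FrozenSet[str] | Set[str]]) -> ParsimonyAssignment:
    """Greedy minimal-cover assignment of every peptide to one protein."""
    totals: Dict[str, int] = {}
    candidates: Dict[str, Set[str]] = {}
    for pep, prots in pm.items():
        if not prots:
            raise ValueError(f"peptide {pep!r} maps to no protein")
        for p in prots:
            totals[p] = totals.get(p, 0) + 1
            candidates.setdefault(p, set()).add(pep)
    unassigned = set(pm)
    assignment: Dict[str, str] = {}
    selected: List[str] = []
    while unassigned:
        best = min(
            candidates,
            key=lambda p: (-len(candidates[p] & unassigned), -totals[p], p),
        )
        covered = candidates[best] & unassigned
        if not covered:  # pragma: no cover - defensive; loop ends first
            break
        for pep in covered:
            assignment[pep] = best
        unassigned -= covered
        selected.append(best)
        del candidates[best]
    return ParsimonyAssignment(assignment=assignment, selected_proteins=selected)


def support_counts(
    assign: ParsimonyAssignment,
    genome_of: Mapping[str, str],
    min_peptides: int = 2,
) -> Dict[str, int]:
    """Per genome, number of proteins with >= min_peptides assigned
    peptides (the 'at least two supporting peptides' criterion)."""
    per_protein: Dict[str, int] = {}
    for prot in assign.assignment.values():
        per_protein[prot] = per_protein.get(prot, 0) + 1
    counts: Dict[str, int] = {}
    for prot, n in per_protein.items():
        if prot not in genome_of:
            raise ValueError(f"protein {prot!r} has no genome mapping")
        if n >= min_peptides:
            g = genome_of[prot]
            counts[g] = counts.get(g, 0) + 1
    return counts


def peptide_genome_spread(
    pm: Mapping[str, FrozenSet[str] | Set[str]],
    genome_of: Mapping[str, str],
) -> Dict[int, int]:
    """Histogram over k = number of genomes whose proteins a peptide
    matches, using the full (pre-parsimony) mapping."""
    hist: Dict[int, int] = {}
    for pep, prots in pm.items():
        genomes = {genome_of[p] for p in prots}
        k = len(genomes)
        hist[k] = hist.get(k, 0) + 1
    return dict(sorted(hist.items()))


def minimal_cover_bruteforce(pm: Mapping[str, FrozenSet[str] | Set[str]]) -> int:
    """Exhaustive minimum set-cover size; exponential, for small test
    fixtures only (<= ~12 peptides)."""
    from itertools import combinations

    proteins = sorted({p for prots in pm.values() for p in prots})
    peptides = set(pm)
    for size in range(1, len(proteins) + 1):
        for combo in combinations(proteins, size):
            covered = set()
            for pep, prots in pm.items():
                if prots & set(combo):
                    covered.add(pep)
            if covered == peptides:
                return size
    return len(proteins)
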