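"""Compare a pangene catalog against another clustering of the same genes
(reciprocal-best-hit ortholog indices, syntenic orthogroups, ...).

For every pangene the best match in the other clustering is the cluster
with the highest Jaccard index over (normalized) gene-id sets.  The
summary reports how many matches are identical and how many exceed each
similarity threshold (default 0.7, i.e. >70% similarity).
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Callable, Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

from .models import PangeneMatrix


@dataclass
class ClusterMatch:
    id_a: str
    id_b: Optional[str]
    jaccard: float
    overlap_over_a: float
    identical: bool


@dataclass
class ComparisonSummary:
    n_a: int
    n_b: int
    n_identical: int
    n_above: Dict[float, int]
    median_size_a: float
    median_size_b: float


def compare_clusterings(
    a: PangeneMatrix,
    b: Mapping[str, Set[str] | FrozenSet[str]],
    thresholds: Sequence[float] = (0.7,),
    normalize: Optional[Callable[[str], str]] = None,
) -> Tuple[List[ClusterMatch], ComparisonSummary]:
    """Best-Jaccard match in ``b`` for each cluster of ``a``.

    ``normalize`` maps gene ids into a shared namespace (transcript-suffix
    stripping, prefix translation) before comparison.  Ties on Jaccard go
    to the lexicographically smaller b-cluster id.
    """
    if len(a) == 0 or not b:
        raise ValueError("cannot compare empty clusterings")
    norm = normalize if normalize is not None else (lambda g: g)
    b_sets: Dict[str, FrozenSet[str]] = {
        bid: frozenset(norm(g) for g in genes) for bid, genes in b.items()
    }
    index: Dict[str, List[str]] = {}
    for bid, genes in b_sets.items():
        for g in genes:
            index.setdefault(g, []).append(bid)

    matches: List[ClusterMatch] = []
    for i, p in enumerate(a.pangenes):
        genes = frozenset(norm(g) for g in p.gene_ids())
        aid = p.pangene_id if p.pangene_id is not None else str(i)
        candidates = {bid for g in genes for bid in index.get(g, [])}
        best_bid, best_j, best_ov = None, 0.0, 0.0
        for bid in sorted(candidates):
            inter = len(genes & b_sets[bid])
            j = inter / len(genes | b_sets[bid])
            if j > best_j:
                best_bid, best_j = bid, j
                best_ov = inter / len(genes)
        matches.append(
            ClusterMatch(
                id_a=aid,
                id_b=best_bid,
                jaccard=best_j,
                overlap_over_a=best_ov,
                identical=best_j == 1.0,
            )
        )
    summary = ComparisonSummary(
        n_a=len(a),
        n_b=len(b),
        n_identical=sum(m.identical for m in matches),
        n_above={t: sum(m.jaccard > t for m in matches) for t in thresholds},
        median_size_a=median(p.n_genes for p in a.pangenes),
        median_size_b=median(len(v) for v in b_sets.values()),
    )
    return matches, summary
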