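"""Recounts over an already-built catalog matrix (e.g. the deposited
release downloaded from its archive), without re-running clustering.

Here a *singleton* is a pangene whose members all come from one genome
(the matrix stores transcript ids, so genome occupancy — not gene count —
is the recountable quantity).
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Dict, Optional

from .models import GenomePanel, PangeneMatrix, Subfamily, make_panel

# varietal group of each panel genome, keyed by gene-model prefix
PANEL_SUBFAMILY_BY_PREFIX: Dict[str, str] = {
    "OsARC": "aromatic",
    "OsAzu": "japonica",
    "OsCMeo": "japonica",
    "OsGoSa": "indica",
    "OsIR64": "indica",
    "OsKeNa": "japonica",
    "OsKYG": "indica",
    "OsLaMu": "indica",
    "OsLima": "indica",
    "OsLiXu": "indica",
    "OsMH63": "indica",
    "OsN22": "aus",
    "OsNaBo": "aus",
    "OsNip": "japonica",   # merged reference column
    "OsPr106": "indica",
    "OsZS97": "indica",
    "Osativa": "japonica",
    "Nipponbare": "japonica",
    "IRGSP": "japonica",
}


def infer_panel(column_names, subfamily_of: Optional[Dict[str, str]] = None) -> GenomePanel:
    """Build a panel from matrix header columns, assigning subfamilies via
    prefix lookup (falls back to indica for unrecognized names)."""
    lookup = dict(PANEL_SUBFAMILY_BY_PREFIX)
    if subfamily_of:
        lookup.update(subfamily_of)
    triples = []
    for name in column_names:
        fam = lookup.get(name)
        if fam is None:
            for pfx, f in lookup.items():
                if name.startswith(pfx):
                    fam = f
                    break
        triples.append((name, name + "_", fam or "indica"))
    return make_panel(triples)


def catalog_counts(
    matrix: PangeneMatrix,
    reference_genome: str,
) -> Dict[str, int]:
    """Headline catalog counts: total pangenes, singleton (one-genome) and
    multi-genome clusters, and pangenes lacking any model from the
    reference genome (overall and at occupancy >= 2)."""
    if reference_genome not in matrix.panel.genome_ids:
        raise ValueError(f"unknown reference genome {reference_genome!r}")
    n_total = len(matrix)
    n_singleton = sum(1 for p in matrix.pangenes if p.occupancy == 1)
    lacking = [p for p in matrix.pangenes if reference_genome not in p.members]
    return {
        "n_pangenes": n_total,
        "n_singletons": n_singleton,
        "n_multi": n_total - n_singleton,
        "n_lacking_reference": len(lacking),
        "n_lacking_reference_occ2plus": sum(1 for p in lacking if p.occupancy >= 2),
    }
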