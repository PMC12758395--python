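#!/usr/bin/env python
"""Recount the published headline numbers from the deposited catalog
release (optional; requires a download).

Expected files under data/deposited/ (see README for the archive record):

* ``pangene_matrix.tsv``  — the released matrix: stable id column plus
  one transcript-id column per genome ("-" for absent).
* ``gene_positions.tsv``  — gene_id, chrom, start for every clustered gene.
* ``domain_summary.tsv``  — pangene_id, representative_pfam,
  n_missing_genomes for multi-member pangenes.

Recomputes: total pangene / singleton / multi-member counts, rows lacking
a reference-genome model, growth-curve asymptotes from 20 permutations,
trans-chromosome pangenes, domain consistency and japonica segregation.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import pandas as pd

from ricepangenes import io as rio
from ricepangenes.deposited import catalog_counts, infer_panel
from ricepangenes.occupancy import (
    fit_growth,
    segregating_pangenes,
    simulate_growth,
    trans_chromosome_pangenes,
)

DATA = Path(__file__).resolve().parent.parent / "data" / "deposited"
SEED = 42


def main() -> int:
    matrix_path = DATA / "pangene_matrix.tsv"
    if not matrix_path.exists():
        print(f"deposited matrix not found at {matrix_path}; download the "
              f"release tables first (see README).", file=sys.stderr)
        return 1
    with open(matrix_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    panel = infer_panel(header[1:])
    matrix = rio.read_pangene_matrix(matrix_path, panel)

    ref = next(g for g in panel.genome_ids
               if any(t in g for t in ("Nip", "Osativa", "IRGSP", "sativa")))
    counts = catalog_counts(matrix, ref)
    for k, v in counts.items():
        print(f"{k}: {v}")

    curve = simulate_growth(matrix, n_permutations=20, seed=SEED)
    for model in ("tettelin", "willenbrock"):
        fit = fit_growth(curve, model, seed=SEED)
        print(f"{model} core asymptote: {fit.omega:.0f}")

    pos_path = DATA / "gene_positions.tsv"
    if pos_path.exists():
        pos = pd.read_csv(pos_path, sep="\t")
        mapping = {r.gene_id: (str(r.chrom), int(r.start))
                   for r in pos.itertuples()}
        hits, skipped = trans_chromosome_pangenes(matrix, mapping)
        print(f"trans-chromosome pangenes (occupancy>2): {len(hits)} "
              f"({skipped} skipped)")

    dom_path = DATA / "domain_summary.tsv"
    if dom_path.exists():
        dom = pd.read_csv(dom_path, sep="\t")
        annotated = dom[dom["representative_pfam"].notna()]
        print(f"Pfam-annotated multi-member pangenes: {len(annotated)}")
        print(f"domain-consistent: "
              f"{(annotated['n_missing_genomes'] == 0).sum()}")
        print(f"NAC (PF02365) pangenes: "
              f"{(annotated['representative_pfam'] == 'PF02365').sum()}")

    fam = panel.subfamily_members("japonica")
    seg = segregating_pangenes(matrix, "japonica", min_in=len(fam), max_out=1)
    print(f"japonica-segregating pangenes: {len(seg)}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
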