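#!/usr/bin/env python
"""Occupancy structure of the catalog: histogram, singletons per genome,
core-genome growth curves (Tettelin and Willenbrock fits over 20
permutation experiments), shared-cluster percentages, subfamily
segregation and trans-chromosome pangenes, plus evidence covariates by
occupancy class (ANOVA + Tukey HSD, core vs cloud).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import importlib

import pandas as pd

sim = importlib.import_module("01_simulate_pangenome")

from ricepangenes.cluster import build_clusters
from ricepangenes.ids import IdScheme, assign_ids
from ricepangenes.occupancy import (
    evidence_by_occupancy,
    fit_growth,
    occupancy_histogram,
    segregating_pangenes,
    shared_cluster_matrix,
    simulate_growth,
    singleton_counts_per_genome,
    trans_chromosome_pangenes,
)
from ricepangenes.synth import generate_pangenome

OUT = Path(__file__).resolve().parent.parent / "results" / "stats"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pg = generate_pangenome(sim.CFG)
    matrix = assign_ids(
        build_clusters(pg.all_genes(), pg.correspondences, pg.panel),
        IdScheme(),
    )

    hist = occupancy_histogram(matrix)
    pd.DataFrame(sorted(hist.items()), columns=["occupancy", "n_pangenes"]) \
        .to_csv(OUT / "occupancy_histogram.tsv", sep="\t", index=False)
    print(f"occupancy histogram: {sum(hist.values())} pangenes, "
          f"{hist.get(16, 0)} at full occupancy")

    singles = singleton_counts_per_genome(matrix)
    pd.DataFrame(sorted(singles.items()), columns=["genome", "n_singletons"]) \
        .to_csv(OUT / "singletons_per_genome.tsv", sep="\t", index=False)
    print(f"singletons per genome: mean "
          f"{sum(singles.values()) / len(singles):.1f}")

    curve = simulate_growth(matrix, n_permutations=20, seed=sim.SEED)
    curve.points.to_csv(OUT / "growth_curve_points.tsv", sep="\t", index=False)
    fits = []
    for model in ("tettelin", "willenbrock"):
        f = fit_growth(curve, model, seed=sim.SEED)
        fits.append((model, f.omega, f.kappa, f.tau, f.residual_ss))
        print(f"{model} core-size asymptote: {f.omega:.0f} genes (tau={f.tau:.2f})")
    pd.DataFrame(fits, columns=["model", "omega", "kappa", "tau", "residual_ss"]) \
        .to_csv(OUT / "growth_fits.tsv", sep="\t", index=False)

    shared = shared_cluster_matrix(matrix)
    shared.to_csv(OUT / "shared_cluster_matrix.tsv", sep="\t")
    print(f"shared-cluster percentage range (off-diagonal): "
          f"{shared.where(shared < 100).min().min():.1f}"
          f"-{shared.where(shared < 100).max().max():.1f}%")

    seg_rows = []
    for fam, min_in in (("japonica", 4), ("aus", 2), ("indica", 9)):
        ids = segregating_pangenes(matrix, fam, min_in=min_in, max_out=1)
        seg_rows.append((fam, min_in, len(ids)))
        print(f"{fam}-segregating pangenes (>= {min_in} in-family, <=1 out): "
              f"{len(ids)}")
    pd.DataFrame(seg_rows, columns=["subfamily", "min_in", "n_pangenes"]) \
        .to_csv(OUT / "segregating_pangenes.tsv", sep="\t", index=False)

    positions = {g.gene_id: (g.chrom, g.start) for g in pg.all_genes()}
    hits, skipped = trans_chromosome_pangenes(matrix, positions)
    Path(OUT / "trans_chromosome_pangenes.txt").write_text(
        "\n".join(hits) + "\n")
    print(f"trans-chromosome pangenes (occupancy>2): {len(hits)} "
          f"(planted translocations with occupancy>2: "
          f"{sum(1 for c in pg.truth.translocated_clusters if pg.truth.planted_occupancy[c] > 2)})")

    for field in ("aed", "expression", "plddt"):
        res = evidence_by_occupancy(matrix, pg.evidence, field)
        res.by_class.to_csv(OUT / f"evidence_{field}_by_class.tsv", sep="\t")
        print(f"{field}: core mean {res.by_class.loc['core', 'mean']:.3g}, "
              f"cloud mean {res.by_class.loc['cloud', 'mean']:.3g}, "
              f"core-vs-cloud Tukey p {res.core_vs_cloud_p:.3g}")
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
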