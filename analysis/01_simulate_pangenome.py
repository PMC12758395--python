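#!/usr/bin/env python
"""Generate the synthetic study pangenome.

Emulates the real panel's shape — 16 genomes over four varietal groups
(4 japonica, 1 aromatic, 2 aus, 9 indica), 12 chromosomes — with 500
core, 100 softcore, 200 shell and 150 cloud planted clusters, 5 planted
translocations, 2 inversions, TE-flagged cloud genes and occupancy-graded
evidence covariates.  Also writes the three overlapping reference-genome
annotation tracks.  Outputs under results/synthetic/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from ricepangenes.synth import SynthConfig, generate_pangenome, generate_reference_tracks

# the raw generated files are bulky and fully regenerable from the seed,
# so they go under scratch/; derived tables live under results/
OUT = Path(__file__).resolve().parent.parent / "scratch" / "synthetic"
SEED = 101

CFG = SynthConfig(n_core=500, n_softcore=100, n_shell=200, n_cloud=150,
                  seed=SEED)


def main() -> None:
    pg = generate_pangenome(CFG, OUT)
    tracks = generate_reference_tracks(CFG, OUT / "reference_tracks")
    print(f"panel: {len(pg.panel)} genomes, "
          f"{sum(len(v) for v in pg.genes.values())} gene models")
    print(f"planted clusters: {len(pg.truth.planted_clusters)} "
          f"({CFG.n_core} core / {CFG.n_softcore} softcore / "
          f"{CFG.n_shell} shell / {CFG.n_cloud} cloud)")
    print(f"correspondence edges: {len(pg.correspondences)} "
          f"({sum(1 for e in pg.correspondences if not e.same_strand)} "
          f"spurious cross-strand)")
    print(f"reference tracks: "
          f"{ {s.value: len(t) for s, t in tracks.tracks.items()} }")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
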