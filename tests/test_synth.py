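"""The synthetic pangenome generator: planted truth, determinism, and the
statistical structure of the generated evidence."""

import filecmp

import numpy as np
import pytest

from ricepangenes.merge import overlap_fraction
from ricepangenes.models import Source
from ricepangenes.synth import (
    ConfigError,
    SynthConfig,
    generate_pangenome,
    generate_reference_tracks,
)


class TestConfigValidation:
    def test_subfamily_sizes_must_sum(self):
        with pytest.raises(ConfigError, match="subfamily"):
            SynthConfig(n_genomes=16, subfamily_sizes={"japonica": 4})

    def test_shell_needs_five_genomes(self):
        with pytest.raises(ConfigError, match="shell"):
            SynthConfig(n_genomes=4,
                        subfamily_sizes={"japonica": 2, "indica": 2},
                        n_shell=10)

    def test_rates_in_unit_interval(self):
        with pytest.raises(ConfigError, match="edge_dropout"):
            SynthConfig(edge_dropout=1.0)


class TestGeneratePangenome:
    def test_planted_occupancy_histogram_exact(self, small_pangenome, small_config):
        occ = list(small_pangenome.truth.planted_occupancy.values())
        n = small_config.n_genomes
        assert occ.count(n) == small_config.n_core
        assert occ.count(n - 1) == small_config.n_softcore
        assert sum(1 for o in occ if 3 <= o <= n - 2) >= small_config.n_shell
        assert sum(1 for o in occ if o <= 2) == small_config.n_cloud

    def test_each_gene_in_exactly_one_cluster(self, small_pangenome):
        seen = {}
        for cid, members in small_pangenome.truth.planted_clusters.items():
            for genes in members.values():
                for g in genes:
                    assert g not in seen
                    seen[g] = cid
        assert len(seen) == len(small_pangenome.all_genes())

    def test_translocations_planted_on_other_chromosomes(self, small_pangenome,
                                                         small_config):
        truth = small_pangenome.truth
        assert len(truth.translocated_clusters) == small_config.planted_translocations
        by_gene = {g.gene_id: g for g in small_pangenome.all_genes()}
        for cid in truth.translocated_clusters:
            chroms = {
                int(by_gene[g].chrom[-2:])
                for genes in truth.planted_clusters[cid].values()
                for g in genes
            }
            assert len(chroms) == 2

    def test_inversions_flip_strand_in_one_genome(self, small_pangenome,
                                                  small_config):
        truth = small_pangenome.truth
        assert len(truth.inverted_clusters) == small_config.planted_inversions
        by_gene = {g.gene_id: g for g in small_pangenome.all_genes()}
        for cid in truth.inverted_clusters:
            strands = [
                by_gene[g].strand
                for genes in truth.planted_clusters[cid].values()
                for g in genes
            ]
            assert "-" in strands and "+" in strands

    def test_te_fraction_zero_means_no_te_genes(self):
        cfg = SynthConfig(n_core=20, n_softcore=5, n_shell=10, n_cloud=10,
                          te_fraction=0.0, planted_translocations=0,
                          planted_inversions=0, seed=2)
        pg = generate_pangenome(cfg)
        assert pg.truth.te_genes == set()
        assert not any(g.is_te for g in pg.all_genes())

    def test_spurious_edges_are_cross_strand_flagged(self, small_pangenome):
        spurious = [e for e in small_pangenome.correspondences if not e.same_strand]
        assert spurious  # default 1% fraction
        gene_cluster = {
            g: cid
            for cid, mem in small_pangenome.truth.planted_clusters.items()
            for genes in mem.values() for g in genes
        }
        for e in spurious:
            assert gene_cluster[e.gene_a] != gene_cluster[e.gene_b]

    def test_same_seed_byte_identical_outputs(self, small_config, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_pangenome(small_config, d1)
        generate_pangenome(small_config, d2)
        files = sorted(p.name for p in d1.iterdir())
        assert files == sorted(p.name for p in d2.iterdir())
        for name in files:
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_subfamily_bias_creates_segregating_clusters(self, small_pangenome):
        """Some shell/cloud clusters are seeded from one varietal group,
        so family-segregating pangenes exist in the truth."""
        pg = small_pangenome
        fams = {
            fam: set(pg.panel.subfamily_members(fam))
            for fam in ("japonica", "indica", "aus")
        }
        n_segregating = 0
        for members in pg.truth.planted_clusters.values():
            genomes = set(members)
            for fam_genomes in fams.values():
                inside = len(genomes & fam_genomes)
                if inside == len(fam_genomes) and len(genomes) - inside <= 1:
                    n_segregating += 1
                    break
        assert n_segregating > 0

    def test_evidence_monotone_in_occupancy(self, small_pangenome):
        pg = small_pangenome
        occ_of = {
            g: pg.truth.planted_occupancy[cid]
            for cid, mem in pg.truth.planted_clusters.items()
            for genes in mem.values() for g in genes
        }
        ev = pg.evidence.set_index("gene_id")
        occ = np.array([occ_of[g] for g in ev.index])
        slope_expr = np.polyfit(occ, ev["expression"].to_numpy(), 1)[0]
        slope_aed = np.polyfit(occ, ev["aed"].to_numpy(), 1)[0]
        slope_plddt = np.polyfit(occ, ev["plddt"].to_numpy(), 1)[0]
        assert slope_expr > 0 and slope_plddt > 0 and slope_aed < 0


class TestReferenceTracks:
    def test_boundary_pairs_straddle_threshold(self, reference_tracks):
        genes = {g.gene_id: g for t in reference_tracks.tracks.values() for g in t}
        fracs = []
        for pair in (s for s in reference_tracks.merge_truth if len(s) == 2):
            a, b = (genes[g] for g in sorted(pair))
            if a.length == 100:
                fracs.append(round(overlap_fraction(a, b), 2))
        # the planted must-merge boundary pairs sit at 0.51
        assert 0.51 in fracs
        # and the planted 0.49 pairs are recorded as two separate genes
        singles = [
            genes[next(iter(s))] for s in reference_tracks.merge_truth
            if len(s) == 1
        ]
        lengths100 = [g for g in singles if g.length == 100]
        assert lengths100  # 0.49 pairs present as non-merging singletons

    def test_msu_only_te_genes_present(self, reference_tracks):
        te = [g for g in reference_tracks.tracks[Source.MSU] if g.is_te]
        assert te

    def test_te_fraction_zero_disables_te(self):
        cfg = SynthConfig(te_fraction=0.0, seed=7)
        tracks = generate_reference_tracks(cfg)
        assert not any(g.is_te for t in tracks.tracks.values() for g in t)

    def test_same_seed_identical_files(self, small_config, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_reference_tracks(small_config, d1)
        generate_reference_tracks(small_config, d2)
        for p in d1.iterdir():
            assert filecmp.cmp(p, d2 / p.name, shallow=False)
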