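"""Representative domains, domain occupancy profiles, TE filtering and
hypergeometric enrichment."""

from itertools import combinations
from math import comb

import pytest

from ricepangenes.domains import (
    categorize_occupancy,
    domain_consistency,
    domain_profiles,
    enrich,
    filter_te_clusters,
    representative_domain,
)
from ricepangenes.models import DomainAssignment, Pangene, PangeneMatrix, make_panel


def da(protein, genome, acc, namespace="Pfam", te=False):
    return DomainAssignment(protein, genome, acc, namespace, te)


@pytest.fixture
def panel4():
    return make_panel([("G1", "G1_", "japonica"), ("G2", "G2_", "indica"),
                       ("G3", "G3_", "aus"), ("G4", "G4_", "aromatic")])


def mk(panel, *member_dicts, ids=True):
    return PangeneMatrix(panel, [
        Pangene(m, f"pan{i:07d}" if ids else None)
        for i, m in enumerate(member_dicts)
    ])


class TestRepresentativeDomain:
    def test_majority_domain_wins(self):
        p = Pangene({"G1": ["a"], "G2": ["b"], "G3": ["c"]})
        sub = [da("a", "G1", "D"), da("b", "G2", "D"), da("c", "G3", "D"),
               da("a", "G1", "E")]
        rep, missing = representative_domain(p, sub)
        assert rep == "D" and missing == set()

    def test_missing_genomes_reported(self):
        p = Pangene({"G1": ["a"], "G2": ["b"], "G3": ["c"]})
        sub = [da("a", "G1", "D"), da("b", "G2", "D")]
        rep, missing = representative_domain(p, sub)
        assert rep == "D" and missing == {"G3"}

    def test_no_domains_gives_none(self):
        p = Pangene({"G1": ["a"]})
        assert representative_domain(p, []) == (None, set())

    def test_tie_break_is_seeded_and_stable(self):
        p = Pangene({"G1": ["a"], "G2": ["b"]})
        sub = [da("a", "G1", "D"), da("b", "G2", "D"),
               da("a", "G1", "E"), da("b", "G2", "E")]
        picks = {representative_domain(p, sub, seed=4)[0] for _ in range(5)}
        assert len(picks) == 1
        assert picks.pop() in {"D", "E"}


class TestConsistency:
    def test_consistent_and_outlier_counting(self, panel4):
        m = mk(panel4,
               {"G1": ["a"], "G2": ["b"]},          # consistent
               {"G1": ["c"], "G2": ["d"], "G3": ["e"]})  # G3 lacks domain
        assignments = [da("a", "G1", "D"), da("b", "G2", "D"),
                       da("c", "G1", "D"), da("d", "G2", "D")]
        rep = domain_consistency(m, assignments)
        assert rep.n_annotated == 2 and rep.n_consistent == 1
        assert rep.outliers_per_genome == {"G1": 0, "G2": 0, "G3": 1, "G4": 0}

    def test_planted_outlier_counts_recovered_exactly(self, small_pangenome,
                                                      small_matrix):
        """Per-genome outlier counts equal the generator's planted
        domain-consistency dropouts plus the regime domains' non-carrier
        genomes."""
        pg = small_pangenome
        rep = domain_consistency(small_matrix, pg.domain_assignments, "Pfam")
        expected = {g: 0 for g in small_matrix.panel.genome_ids}
        for cid, outliers in pg.truth.domain_outlier_genomes.items():
            for genome in outliers:
                expected[genome] += len(pg.truth.planted_clusters[cid][genome])
        for (acc, cid), carriers in pg.truth.regime_carriers.items():
            for genome in pg.truth.planted_clusters[cid]:
                if genome not in carriers:
                    expected[genome] += len(pg.truth.planted_clusters[cid][genome])
        assert rep.outliers_per_genome == expected
        n_inconsistent_truth = (
            sum(1 for o in pg.truth.domain_outlier_genomes.values() if o)
            + len({cid for (acc, cid), carriers in pg.truth.regime_carriers.items()
                   if set(pg.truth.planted_clusters[cid]) - carriers})
        )
        assert rep.n_annotated - rep.n_consistent == n_inconsistent_truth

    def test_planted_domain_occupancy_recovered(self, small_pangenome, small_matrix):
        pg = small_pangenome
        gene_cluster = {
            g: cid for cid, members in pg.truth.planted_clusters.items()
            for genes in members.values() for g in genes
        }
        profiles = domain_profiles(small_matrix, pg.domain_assignments,
                                   "Pfam", min_pangenes=1)
        by_acc = {p.domain_acc: p for p in profiles}
        for (acc, cid), occ in pg.truth.planted_domain_occupancy.items():
            prof = by_acc[acc]
            rows = {
                key: v for key, v in prof.per_pangene_occupancy.items()
            }
            # find the matrix row holding this planted cluster
            row_key = next(
                key for key, v in rows.items()
                if gene_cluster[
                    small_matrix.pangenes[int(key)].gene_ids()[0]
                ] == cid
            )
            assert rows[row_key] == occ


class TestProfiles:
    def test_mean_and_category_arithmetic(self, panel4):
        # 5 pangenes carrying the domain with occupancies 1,1,16-like mix
        panel = make_panel([(f"g{i}", f"g{i}_", "indica") for i in range(16)])
        members = []
        occs = [1, 1, 16, 16, 1]
        assignments = []
        for i, occ in enumerate(occs):
            genomes = [f"g{j}" for j in range(occ)]
            members.append({g: [f"{g}_x{i}"] for g in genomes})
            assignments += [da(f"{g}_x{i}", g, "DOM") for g in genomes]
        m = mk(panel, *members)
        profs = domain_profiles(m, assignments, min_pangenes=5)
        assert len(profs) == 1
        assert profs[0].mean_occupancy == pytest.approx(7.0)
        assert profs[0].category == "highly_variable"

    def test_min_pangenes_filter(self, panel4):
        members = [{"G1": [f"G1_x{i}"]} for i in range(4)]
        assignments = [da(f"G1_x{i}", "G1", "DOM") for i in range(4)]
        m = mk(panel4, *members)
        assert domain_profiles(m, assignments, min_pangenes=5) == []
        assert len(domain_profiles(m, assignments, min_pangenes=4)) == 1

    @pytest.mark.parametrize("mean,expected", [
        (9.999, "highly_variable"),
        (10.0, "partially_variable"),
        (14.999, "partially_variable"),
        (15.0, "invariable"),
        (16.0, "invariable"),
    ])
    def test_category_boundaries(self, mean, expected):
        assert categorize_occupancy(mean) == expected


class TestTeFilter:
    def test_occupancy_dependent_rules(self, panel4):
        m = mk(panel4,
               {"G1": ["te_single"]},                    # TE singleton: drop
               {"G1": ["flag_single"]},                  # annotation flag: drop
               {"G1": ["clean_single"]},                 # keep
               {"G1": ["m1"], "G2": ["m2"], "G3": ["m3"]},   # 1/3 TE: keep
               {"G1": ["t1"], "G2": ["t2"]})             # all TE: drop
        assignments = [da("te_single", "G1", "TEDOM", te=True),
                       da("m1", "G1", "TEDOM", te=True),
                       da("t1", "G1", "TEDOM", te=True),
                       da("t2", "G2", "TEDOM", te=True)]
        out = filter_te_clusters(m, assignments, te_flags={"flag_single": True})
        assert [p.pangene_id for p in out.pangenes] == ["pan0000002", "pan0000003"]

    def test_annotation_flag_does_not_remove_multi_clusters(self, panel4):
        m = mk(panel4, {"G1": ["x1"], "G2": ["x2"]})
        out = filter_te_clusters(m, [], te_flags={"x1": True, "x2": True})
        assert len(out) == 1  # occupancy>1 needs domain evidence on all members


class TestEnrich:
    def test_closed_form_extreme_case(self):
        # N=20, K=5, n=5, k=5 -> C(5,5)C(15,0)/C(20,5) = 1/15504
        background = {f"p{i}" for i in range(20)}
        foreground = {f"p{i}" for i in range(5)}
        term_map = {f"p{i}": {"T"} for i in range(5)}
        res = enrich(foreground, background, term_map)
        assert len(res) == 1
        assert res[0].p == pytest.approx(1 / 15504, rel=1e-9)
        assert res[0].gene_ratio == 1.0

    def test_matches_exhaustive_enumeration(self):
        # exact upper-tail by enumerating all C(N, n) foreground draws
        N, K, n = 12, 5, 4
        background = [f"p{i}" for i in range(N)]
        positives = set(background[:K])
        foreground = set(background[2:2 + n])  # overlaps positives in 3
        k = len(foreground & positives)
        total = hits = 0
        for draw in combinations(background, n):
            total += 1
            if len(set(draw) & positives) >= k:
                hits += 1
        expected = hits / total
        res = enrich(foreground, set(background),
                     {p: {"T"} for p in positives})
        assert res[0].p == pytest.approx(expected, rel=1e-9)

    def test_foreground_equals_background_gives_p_one(self):
        bg = {"a", "b", "c"}
        res = enrich(bg, bg, {"a": {"T"}, "b": {"T"}})
        assert res[0].p == pytest.approx(1.0)

    def test_zero_hits_gives_p_one(self):
        res = enrich({"a"}, {"a", "b", "c"}, {"b": {"T"}})
        assert res[0].p == pytest.approx(1.0)

    def test_bh_adjustment_monotone_and_above_raw(self):
        background = {f"p{i}" for i in range(30)}
        foreground = {f"p{i}" for i in range(6)}
        term_map = {}
        for i in range(6):
            term_map.setdefault(f"p{i}", set()).add("STRONG")
        for i in range(3, 20):
            term_map.setdefault(f"p{i}", set()).add("WEAK")
        for i in range(10, 14):
            term_map.setdefault(f"p{i}", set()).add("NONE")
        res = enrich(foreground, background, term_map)
        for r in res:
            assert r.p_adj >= r.p - 1e-15
        in_p_order = sorted(res, key=lambda r: r.p)
        adj = [r.p_adj for r in in_p_order]
        assert adj == sorted(adj)

    def test_foreground_not_subset_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            enrich({"x"}, {"a"}, {})
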