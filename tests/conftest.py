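import pytest

from ricepangenes.cluster import build_clusters
from ricepangenes.models import GeneModel, Source, make_panel
from ricepangenes.synth import SynthConfig, generate_pangenome, generate_reference_tracks


def gene(
    gene_id,
    start,
    end,
    strand="+",
    chrom="Chr01",
    genome="G1",
    source=Source.PIPELINE,
    coding=True,
    te=False,
):
    return GeneModel(
        gene_id=gene_id,
        genome=genome,
        source=Source(source),
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        transcript_ids=(gene_id + ".t1",) if coding else (),
        is_coding=coding,
        is_te=te,
    )


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study conditions: 16 genomes, 4 subfamilies, planted
    occupancy mix, no edge dropout."""
    return SynthConfig(
        n_core=60, n_softcore=15, n_shell=25, n_cloud=20,
        planted_translocations=3, planted_inversions=2, seed=11,
    )


@pytest.fixture(scope="session")
def small_pangenome(small_config):
    return generate_pangenome(small_config)


@pytest.fixture(scope="session")
def small_matrix(small_pangenome):
    pg = small_pangenome
    return build_clusters(pg.all_genes(), pg.correspondences, pg.panel)


@pytest.fixture(scope="session")
def reference_tracks(small_config):
    return generate_reference_tracks(small_config)


@pytest.fixture(scope="session")
def tiny_panel():
    return make_panel([("G1", "G1_", "japonica"), ("G2", "G2_", "indica"),
                       ("G3", "G3_", "aus")])
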