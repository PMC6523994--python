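import pytest

from patseq import SimConfig, generate_genome, simulate_tags


@pytest.fixture(scope="session")
def small_sim():
    """Jitter-free 20-gene dataset with known truth, shared across tests."""
    cfg = SimConfig(
        n_genes=20, n_switch_genes=2, expression_mean=100,
        cleavage_jitter_sd=0.0, seed=7,
    )
    genome, gff3, truth = generate_genome(cfg)
    tags = simulate_tags(genome, truth, cfg)
    return {"config": cfg, "genome": genome, "gff3": gff3, "truth": truth, "tags": tags}


@pytest.fixture(scope="session")
def small_gff(tmp_path_factory, small_sim):
    path = tmp_path_factory.mktemp("ann") / "genes.gff3"
    path.write_text(small_sim["gff3"])
    return str(path)


@pytest.fixture(scope="session")
def sample_ids(small_sim):
    return [s for s, _, _ in small_sim["config"].samples()]
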