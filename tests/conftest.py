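import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_genome(tmp_path_factory):
    """A small three-gene reference with FASTA/GFF3 on disk."""
    from breedvar.simulate import make_toy_genome

    out = tmp_path_factory.mktemp("toy")
    return make_toy_genome(n_genes=3, gene_length=420, intergenic_length=6000, seed=11, out_dir=out)


@pytest.fixture(scope="session")
def cohort_sim(toy_genome):
    from breedvar.simulate import CohortSpec, simulate_cohort

    return simulate_cohort(
        CohortSpec(n_ingroup=5, n_variants_per_sample=1000, seed=7),
        sequence=toy_genome.sequence,
    )
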