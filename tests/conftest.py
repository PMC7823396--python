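import pytest

from rgascape.io_formats import AnalysisConfig, GeneModel
from rgascape.pipeline import run_pipeline
from rgascape.synthetic_genome import (
    SimConfig,
    paper_counts_fixture,
    simulate_world,
)


@pytest.fixture(scope="session")
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def paper_world():
    return paper_counts_fixture()


@pytest.fixture(scope="session")
def paper_bundle(paper_world):
    return run_pipeline(
        paper_world.species_inputs(), paper_world.pairings, paper_world.cfg
    )


@pytest.fixture(scope="session")
def sim_world():
    return simulate_world(SimConfig(rng_seed=11))


@pytest.fixture(scope="session")
def sim_bundle(sim_world):
    return run_pipeline(sim_world.species_inputs(), sim_world.pairings, sim_world.cfg)


def make_gene(
    gene_id: str,
    chromosome: str = "A01",
    start: int = 1000,
    end: int | None = None,
    species: str = "sp",
    sub_genome: str | None = None,
) -> GeneModel:
    if end is None:
        end = start + 999
    if sub_genome is None:
        sub_genome = AnalysisConfig().subgenome_of(chromosome)
    return GeneModel(
        gene_id=gene_id,
        species=species,
        chromosome=chromosome,
        start=start,
        end=end,
        strand="+",
        sub_genome=sub_genome,
    )
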