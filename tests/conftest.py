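import pytest

from dnvkit import datasets
from dnvkit.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def table1_candidates():
    """Bundled 34-variant candidate table (36-proband cohort)."""
    return datasets.ocd_trio_dnsnvs()


@pytest.fixture(scope="session")
def small_cohort():
    """A desk-scale synthetic cohort shared across read-only tests."""
    cfg = SimulationConfig(
        seed=11, n_trios=8, n_inherited_sites=300, n_x_sites=120, n_genes=60
    )
    sites, pedigree, phenotypes, truth = simulate_cohort(cfg)
    return {
        "config": cfg,
        "sites": sites,
        "pedigree": pedigree,
        "phenotypes": phenotypes,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def study_cohort():
    """A cohort at the study's scale: 36 trios, defaults throughout."""
    cfg = SimulationConfig(seed=2026)
    sites, pedigree, phenotypes, truth = simulate_cohort(cfg)
    return {
        "config": cfg,
        "sites": sites,
        "pedigree": pedigree,
        "phenotypes": phenotypes,
        "truth": truth,
    }
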