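import pytest

from cazykit import datasets, frequency, simulate
from cazykit.model import DomainHit, GeneAnnotation, GenomeSummary, parse_family


def gene(species, gid, families):
    return GeneAnnotation(
        species_id=species,
        gene_id=gid,
        hits=[DomainHit(family=parse_family(f)) for f in families],
    )


@pytest.fixture(scope="session")
def census():
    return datasets.load_plant_census()


@pytest.fixture()
def tiny_annotations():
    """Two hand-built species covering single/repeat/mixed genes."""
    return {
        "SpA": [
            gene("SpA", "a1", ["GT2", "GT2"]),
            gene("SpA", "a2", ["GT2", "GH9"]),
            gene("SpA", "a3", ["GT41"] * 7),
            gene("SpA", "a4", ["CBM43", "GH17"]),
            gene("SpA", "a5", ["GH19"]),
        ],
        "SpB": [
            gene("SpB", "b1", ["GT2"]),
            gene("SpB", "b2", ["CBM18", "GH19", "CBM18"]),
            gene("SpB", "b3", ["CE1", "CE10"]),
        ],
    }


@pytest.fixture()
def tiny_summaries():
    return {
        "SpA": GenomeSummary(species_id="SpA", total_genes=100, lineage_group="eudicot"),
        "SpB": GenomeSummary(species_id="SpB", total_genes=80, lineage_group="monocot"),
    }


def small_config(seed, **overrides):
    """A fast 2-species design with reduced family pools."""
    defaults = dict(
        seed=seed,
        n_species=2,
        n_genes=2_000,
        n_cazyme_genes=250,
        core_family_count=20,
        restricted_family_count=10,
        family_pool_sizes={"GT": 20, "GH": 25, "PL": 5, "CE": 6, "CBM": 10},
    )
    defaults.update(overrides)
    return simulate.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def default_sim():
    """One full-size simulated dataset (5 species x 2,000 CAZyme genes)."""
    cfg = simulate.SimulationConfig(seed=7)
    annotations, summaries, truth = simulate.simulate_annotations(cfg)
    return cfg, annotations, summaries, truth


@pytest.fixture(scope="session")
def default_profiles(default_sim):
    _cfg, annotations, summaries, _truth = default_sim
    return [
        frequency.build_profile(annotations[sp], summaries[sp]) for sp in annotations
    ]
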