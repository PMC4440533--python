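"""Complexity parameter: gene categories, multiplicity, power law, combinations."""

from collections import Counter

import pytest

from cazykit import complexity
from conftest import gene, small_config
from cazykit import simulate


@pytest.fixture()
def records(tiny_annotations):
    return complexity.classify_genes(tiny_annotations)


def test_categories(records):
    by_gene = records.set_index(["species_id", "gene_id"])["category"]
    assert by_gene[("SpA", "a3")] == "repeat_only"  # seven GT41 repeats
    assert by_gene[("SpA", "a4")] == "mixed"  # CBM43 + GH17
    assert by_gene[("SpB", "b1")] == "single"
    assert by_gene[("SpB", "b2")] == "mixed"  # CBM18-GH19-CBM18


def test_category_partition(records):
    import numpy as np

    fracs = complexity.category_fractions(records)
    assert np.allclose(
        fracs[["frac_single", "frac_repeat_only", "frac_mixed"]].sum(axis=1), 1.0
    )
    counts = records.groupby("species_id")["category"].value_counts().unstack(fill_value=0)
    assert (counts.sum(axis=1) == records.groupby("species_id").size()).all()


def test_multiplicity_distribution():
    import pandas as pd

    rec = pd.DataFrame({"n_domains": [1, 1, 1, 2, 3]})
    dist = complexity.multiplicity_distribution(rec)
    assert dist.to_dict() == {1: 3, 2: 1, 3: 1}
    assert dist.sum() == len(rec)
    assert complexity.multiplicity_distribution(rec.iloc[:0]).empty


def test_high_multiplicity_genes_flagged(tiny_annotations):
    big = complexity.families_in_high_multiplicity_genes(tiny_annotations, min_domains=5)
    assert big == {"SpA/a3": {"GT41"}}
    assert all("GT41" in fams for fams in big.values())


def test_fit_power_law_exact():
    dist = {k: 1000 * k**-2 for k in range(1, 7)}
    fit = complexity.fit_power_law(dist)
    assert fit.slope == pytest.approx(-2.0, abs=1e-9)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-9)


def test_fit_power_law_flat_counts():
    fit = complexity.fit_power_law({1: 10, 2: 10, 3: 10})
    assert fit.slope == pytest.approx(0.0, abs=1e-12)
    assert fit.r_squared == 1.0


def test_fit_power_law_needs_two_bins():
    with pytest.raises(ValueError, match="insufficient support"):
        complexity.fit_power_law({3: 17})
    # zero bins are excluded before the check
    with pytest.raises(ValueError, match="insufficient support"):
        complexity.fit_power_law({1: 5, 2: 0, 3: 0})


def test_power_law_exponent_recovery():
    """Slope recovered within +/-0.2 from 5,000 genes drawn at exponent 1.8."""
    gamma = 1.8
    pm = simulate.power_law_consistent_p_multidomain(gamma, 7)
    cfg = simulate.SimulationConfig(
        seed=5, n_species=1, n_cazyme_genes=5000,
        p_multidomain=pm, multiplicity_exponent=gamma,
    )
    ann, _summ, _truth = simulate.simulate_annotations(cfg)
    dist = complexity.multiplicity_distribution(complexity.classify_genes(ann))
    fit = complexity.fit_power_law(dist)
    assert fit.slope == pytest.approx(-gamma, abs=0.2)


def test_combinations_identity_is_distinct_family_set(tiny_annotations):
    catalogs = complexity.combinations(tiny_annotations)
    # repeats within the gene do not change the combination
    assert catalogs["SpB"].combos == Counter(
        {frozenset({"CBM18", "GH19"}): 1, frozenset({"CE1", "CE10"}): 1}
    )
    assert catalogs["SpA"].labels() == {"CBM43+GH17": 1, "GH9+GT2": 1}
    assert catalogs["SpA"].n_mixed_genes == 2


def test_combinations_counts_repeated_combo():
    annots = {"S": [gene("S", f"g{i}", ["CE1", "CE10"]) for i in range(12)]}
    cat = complexity.combinations(annots)["S"]
    assert cat.combos == Counter({frozenset({"CE1", "CE10"}): 12})


def test_no_mixed_genes_empty_catalog():
    annots = {"S": [gene("S", "g1", ["GT2"]), gene("S", "g2", ["GT41"] * 3)]}
    assert complexity.combinations(annots)["S"].combos == Counter()


def test_pairwise_projection():
    cat = complexity.CombinationCatalog(
        "S", Counter({frozenset({"GT2", "GH9", "CBM1"}): 2})
    )
    pairs = complexity.pairwise_projection(cat)
    assert pairs == Counter(
        {
            frozenset({"GT2", "GH9"}): 2,
            frozenset({"GT2", "CBM1"}): 2,
            frozenset({"GH9", "CBM1"}): 2,
        }
    )


def test_compare_combinations_set_algebra():
    a = complexity.CombinationCatalog("A", Counter({frozenset({"GT2", "GH9"}): 1, frozenset({"CE1", "CE7"}): 2}))
    b = complexity.CombinationCatalog("B", Counter({frozenset({"CE1", "CE7"}): 1, frozenset({"PL1", "GH28"}): 1}))
    result = complexity.compare_combinations({"A": a, "B": b})
    grp = result["all"]
    assert grp["shared"] == ["CE1+CE7"]
    assert grp["unique"]["A"]["combinations"] == ["GH9+GT2"]
    assert grp["unique"]["B"]["combinations"] == ["GH28+PL1"]

    same = complexity.compare_combinations({"A": a, "B": a})
    assert same["all"]["n_shared"] == 2
    assert same["all"]["unique"]["A"]["n_unique"] == 0

    with pytest.raises(KeyError, match="unknown species"):
        complexity.compare_combinations({"A": a, "B": b}, {"grp": ["A", "C"]})


def brute_force_catalog(genes):
    """Independent re-scan: count distinct-family sets of multi-family genes."""
    combos = Counter()
    for g in genes:
        fams = set()
        for hit in g.hits:
            fams.add(hit.family.name)
        if len(fams) >= 2:
            combos[frozenset(fams)] += 1
    return combos


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_combinations_match_brute_force_on_synthetic(seed):
    ann, _summ, _truth = simulate.simulate_annotations(small_config(seed))
    catalogs = complexity.combinations(ann)
    for sp, genes in ann.items():
        assert catalogs[sp].combos == brute_force_catalog(genes)


@pytest.mark.parametrize("seed", [0, 1])
def test_planted_categories_recovered(seed):
    ann, _summ, truth = simulate.simulate_annotations(small_config(seed))
    records = complexity.classify_genes(ann)
    for row in records.itertuples(index=False):
        assert truth.gene_category[f"{row.species_id}/{row.gene_id}"] == row.category
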