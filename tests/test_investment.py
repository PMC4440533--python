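"""Expression investment: replicate averaging, the distinct-family
accounting rule, shares, ratios and cross-species direction concordance."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cazykit import investment
from cazykit.model import CLASS_LABELS
from conftest import gene


def expr_df(rows):
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "replicate", "fpkm"])


def test_average_replicates():
    df = expr_df(
        [("g1", "xylem", 1, 10.0), ("g1", "xylem", 2, 20.0), ("g1", "xylem", 3, 30.0),
         ("g2", "xylem", 1, 5.0), ("g3", "leaf", 1, 0.0)]
    )
    m = investment.average_replicates(df)
    assert m.loc["g1", "xylem"] == 20.0
    assert m.loc["g2", "xylem"] == 5.0  # single replicate is its own mean
    assert m.loc["g3", "leaf"] == 0.0
    # mean over available replicates when one is missing
    df2 = expr_df([("g1", "xylem", 1, 10.0), ("g1", "xylem", 2, 20.0)])
    assert investment.average_replicates(df2).loc["g1", "xylem"] == 15.0


def test_expressed_genes_threshold():
    annots = {"S": [gene("S", "g1", ["GT2"]), gene("S", "g2", ["GH9"]), gene("S", "g3", ["PL1"])]}
    m = pd.DataFrame(
        {"phloem": [0.1, 0.0, 0.5], "leaf": [0.0, 0.0, 0.2]}, index=["g1", "g2", "g3"]
    )
    res = investment.expressed_genes(m, annots, threshold=0.0)
    assert res["genes"] == {"g1", "g3"}
    assert res["pct_expressed"] == pytest.approx(2 / 3 * 100)
    res = investment.expressed_genes(m, annots, threshold=1.0)
    assert res["genes"] == set()  # max 0.5 below threshold 1.0


def test_family_investment_repeat_collapse():
    """A gene of seven GT41 repeats adds its FPKM once, not seven times."""
    annots = {"S": [gene("S", "g1", ["GT41"] * 7)]}
    m = pd.DataFrame({"xylem": [100.0]}, index=["g1"])
    t = investment.family_investment(m, annots)
    assert t.loc["GT41", "xylem"] == 100.0


def test_family_investment_mixed_gene_counts_each_family_once():
    """X-X-Y accounting: FPKM added once to X and once to Y."""
    annots = {"S": [gene("S", "g1", ["GH17", "GH17", "CBM43"])]}
    m = pd.DataFrame({"xylem": [50.0]}, index=["g1"])
    t = investment.family_investment(m, annots)
    assert t.loc["GH17", "xylem"] == 50.0
    assert t.loc["CBM43", "xylem"] == 50.0


def test_family_investment_sums_over_genes():
    annots = {"S": [gene("S", "g1", ["GT2"]), gene("S", "g2", ["GT2"])]}
    m = pd.DataFrame({"xylem": [10.0, 5.0]}, index=["g1", "g2"])
    assert investment.family_investment(m, annots).loc["GT2", "xylem"] == 15.0


def test_unannotated_and_unexpressed_genes():
    annots = {"S": [gene("S", "g1", ["GT2"]), gene("S", "g2", ["GH9"])]}
    # matrix has an unannotated gene and lacks g2 entirely
    m = pd.DataFrame({"xylem": [10.0, 99.0]}, index=["g1", "not_annotated"])
    t = investment.family_investment(m, annots)
    assert t.loc["GT2", "xylem"] == 10.0
    assert t.loc["GH9", "xylem"] == 0.0


@given(st.data())
@settings(max_examples=30, deadline=None)
def test_accounting_identity_property(data):
    """Family totals equal sum over genes of meanFPKM x n_distinct_families."""
    n_genes = data.draw(st.integers(1, 8))
    fams = ["GT2", "GH9", "PL1", "CE1", "CBM43"]
    annots = {"S": []}
    fpkm = {}
    for i in range(n_genes):
        chosen = data.draw(st.lists(st.sampled_from(fams), min_size=1, max_size=4))
        annots["S"].append(gene("S", f"g{i}", chosen))
        fpkm[f"g{i}"] = data.draw(
            st.floats(0, 1e4, allow_nan=False, allow_infinity=False)
        )
    m = pd.DataFrame({"xylem": pd.Series(fpkm)})
    t = investment.family_investment(m, annots)
    oracle = sum(
        fpkm[g.gene_id] * len(g.distinct_families) for g in annots["S"]
    )
    assert t["xylem"].sum() == pytest.approx(oracle, rel=1e-9, abs=1e-9)


def test_duplicating_a_repeat_domain_is_a_no_op():
    m = pd.DataFrame({"xylem": [7.0], "leaf": [3.0]}, index=["g1"])
    base = investment.family_investment(m, {"S": [gene("S", "g1", ["GT2", "GH9"])]})
    dup = investment.family_investment(m, {"S": [gene("S", "g1", ["GT2", "GT2", "GH9"])]})
    pd.testing.assert_frame_equal(base, dup)


def test_zero_fpkm_gene_changes_nothing():
    annots = {"S": [gene("S", "g1", ["GT2"])]}
    m1 = pd.DataFrame({"xylem": [10.0]}, index=["g1"])
    base = investment.family_investment(m1, annots)
    annots2 = {"S": annots["S"] + [gene("S", "g2", ["GT2", "GH9"])]}
    m2 = pd.DataFrame({"xylem": [10.0, 0.0]}, index=["g1", "g2"])
    t = investment.family_investment(m2, annots2)
    assert t.loc["GT2", "xylem"] == base.loc["GT2", "xylem"]
    assert t.loc["GH9", "xylem"] == 0.0


def test_class_investment_partitions_families():
    annots = {"S": [gene("S", "g1", ["GT2", "GH9"]), gene("S", "g2", ["GT41"])]}
    m = pd.DataFrame({"xylem": [10.0, 5.0]}, index=["g1", "g2"])
    t = investment.family_investment(m, annots)
    c = investment.class_investment(t)
    assert c.loc["GT", "xylem"] == 15.0  # GT2 10 + GT41 5
    assert c.loc["GH", "xylem"] == 10.0  # the mixed gene invests in GH too
    assert c["xylem"].sum() == t["xylem"].sum()


def test_proportional_investment_shares():
    t = pd.DataFrame(
        {"xylem": [40.0, 30.0, 2.0, 18.0, 10.0]},
        index=pd.Index(["GT2", "GH9", "PL1", "CE1", "CBM43"], name="family"),
    )
    shares = investment.proportional_investment(t)
    assert shares["xylem"].tolist() == [40, 30, 2, 18, 10]
    assert shares["xylem"].sum() == pytest.approx(100)
    single = investment.proportional_investment(t.iloc[[0]])
    assert single.loc["GT2", "xylem"] == 100.0
    by_class = investment.proportional_investment(t, by_class=True)
    assert by_class["xylem"].sum() == pytest.approx(100)


def test_proportional_investment_zero_tissue_absent():
    t = pd.DataFrame({"xylem": [0.0]}, index=["GT2"])
    assert np.isnan(investment.proportional_investment(t).loc["GT2", "xylem"])


def test_tissue_ratio():
    t = pd.DataFrame({"xylem": [190.0, 5.0], "leaf": [100.0, 0.0]}, index=["PL1", "GH4"])
    assert investment.tissue_ratio(t, "PL1", "xylem", "leaf") == pytest.approx(1.9)
    assert investment.tissue_ratio(t, "PL1", "leaf", "leaf") == 1.0
    with pytest.warns(UserWarning, match="infinite"):
        assert math.isinf(investment.tissue_ratio(t, "GH4", "xylem", "leaf"))


def _table(index, xylem, leaf):
    return pd.DataFrame({"xylem": xylem, "leaf": leaf}, index=index)


def test_concordance_labels():
    a = _table(["GT2", "CE8", "GH4", "GH57", "CE15"],
               [10, 1, 0, 2, 3], [5, 9, 0, 1, 1])
    b = _table(["GT2", "CE8", "GH4", "GH57", "CE15"],
               [20, 30, 4, 0, 0], [10, 3, 2, 0, 0])
    conc = investment.concordance(a, b, ("xylem", "leaf"))
    assert conc.loc["GT2", "label"] == "same_xylem_up"
    assert conc.loc["CE8", "label"] == "discordant"  # opposite trends
    assert conc.loc["GH4", "label"] == "absent_in_one"  # zero in species a only
    assert conc.loc["GH57", "label"] == "absent_in_one"
    assert conc.loc["CE15", "label"] == "absent_in_one"


def test_concordance_leaf_up_and_absent_in_both():
    a = _table(["GT1", "GH80"], [1, 0], [9, 0])
    b = _table(["GT1", "GH80"], [2, 0], [3, 0])
    conc = investment.concordance(a, b, ("xylem", "leaf"))
    assert conc.loc["GT1", "label"] == "same_leaf_up"
    assert conc.loc["GH80", "label"] == "absent_in_both"


def test_concordance_never_compares_magnitudes():
    # species b values scaled 1000x: labels must be unchanged
    a = _table(["GT2", "GT1"], [10, 1], [5, 2])
    b = _table(["GT2", "GT1"], [0.02, 0.001], [0.01, 0.002])
    b_scaled = b * 1000
    c1 = investment.concordance(a, b, ("xylem", "leaf"))
    c2 = investment.concordance(a, b_scaled, ("xylem", "leaf"))
    pd.testing.assert_frame_equal(c1, c2)
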