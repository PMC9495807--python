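"""Indicator-value statistic, selection, permutation inference, and the
printed-table consistency solver."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import copeind as ci
from copeind.errors import ValidationError
from conftest import constant_group_matrix, groups_from_sizes


def _cell(table, taxon, group, col="indval"):
    sub = table[(table["taxon"] == taxon) & (table["group"] == group)]
    return float(sub[col].iloc[0])


def test_perfect_indicator_scores_100():
    ids, part = groups_from_sizes((3, 4, 5))
    vals = pd.DataFrame(0.0, index=ids, columns=["tax"])
    vals.loc[part.members("B"), "tax"] = 7.5
    table = ci.indval_table(ci.AbundanceMatrix(vals), part)
    assert _cell(table, "tax", "B") == pytest.approx(100.0)
    assert _cell(table, "tax", "A") == 0.0
    assert _cell(table, "tax", "C") == 0.0


def test_printed_mixed_water_row_reproduced():
    """Group-mean abundances (8.74, 21.31, 8.56) with presence at every
    mixed-water station give IndVal 100*21.31/38.61 = 55.19."""
    abund, part = constant_group_matrix((8.74, 21.31, 8.56), (6, 11, 8))
    table = ci.indval_table(abund, part)
    assert round(_cell(table, "tax", "B"), 2) == 55.19
    assert _cell(table, "tax", "B", "fidelity") == 1.0


def test_printed_cold_water_row_with_partial_fidelity():
    """Group means (78.28, 16.07, 0.10), presence at 5 of 6 cold-water
    stations: IndVal = 100*(78.28/94.45)*(5/6) = 69.07 (printed 69.06
    within rounding of the printed abundances)."""
    ids, part = groups_from_sizes((6, 11, 8))
    vals = pd.DataFrame(0.0, index=ids, columns=["tax"])
    a = part.members("A")
    # 5 occupied stations carry 6/5 of the group mean; one is empty
    vals.loc[a[:5], "tax"] = 78.28 * 6 / 5
    vals.loc[part.members("B"), "tax"] = 16.07
    vals.loc[part.members("C"), "tax"] = 0.10
    table = ci.indval_table(ci.AbundanceMatrix(vals), part)
    assert _cell(table, "tax", "A", "fidelity") == pytest.approx(5 / 6)
    assert _cell(table, "tax", "A") == pytest.approx(
        100.0 * (78.28 / (78.28 + 16.07 + 0.10)) * 5 / 6, abs=1e-9
    )
    assert abs(_cell(table, "tax", "A") - 69.06) < 0.02


def test_absent_taxon_flagged_zero():
    ids, part = groups_from_sizes((3, 3))
    vals = pd.DataFrame({"ghost": 0.0, "real": 1.0}, index=ids)
    table = ci.indval_table(ci.AbundanceMatrix(vals), part)
    ghost = table[table["taxon"] == "ghost"]
    assert (ghost["indval"] == 0).all()
    assert ghost["absent_everywhere"].all()


def test_specificity_sums_to_one_and_scale_invariance(default_survey):
    abund, _, _, truth = default_survey
    table = ci.indval_table(abund, truth.partition)
    occurring = table.groupby("taxon")["summed_group_means"].first() > 0
    sums = table.groupby("taxon")["specificity"].sum()
    assert np.allclose(sums[occurring], 1.0)
    scaled = ci.AbundanceMatrix(abund.data * 3.7)
    table2 = ci.indval_table(scaled, truth.partition)
    assert np.allclose(table["indval"], table2["indval"])


def test_indval_100_iff_perfect_specificity_and_fidelity(default_survey):
    abund, _, _, truth = default_survey
    table = ci.indval_table(abund, truth.partition)
    at_100 = table["indval"] >= 100.0 - 1e-9
    perfect = (table["specificity"] >= 1 - 1e-12) & (table["fidelity"] == 1.0)
    assert (at_100 == perfect).all()


def test_selection_strictly_greater_than_threshold():
    ids, part = groups_from_sizes((2, 2))
    vals = pd.DataFrame(0.0, index=ids, columns=["edge"])
    # present at 1 of 2 group-A stations, absent elsewhere: IndVal exactly 50
    vals.iloc[0, 0] = 4.0
    table = ci.indval_table(ci.AbundanceMatrix(vals), part)
    assert _cell(table, "edge", "A") == pytest.approx(50.0)
    assert ci.select_indicators(table, threshold=50.0).empty
    sel = ci.select_indicators(table, threshold=49.9)
    assert list(sel["taxon"]) == ["edge"]


def test_selection_sorted_descending_within_group(default_survey):
    abund, _, _, truth = default_survey
    table = ci.indval_table(abund, truth.partition)
    sel = ci.select_indicators(table, threshold=50.0)
    for _, sub in sel.groupby("group"):
        assert list(sub["indval"]) == sorted(sub["indval"], reverse=True)
    tiny = ci.select_indicators(table, threshold=1e-6)
    assert set(tiny["group"]) == set(truth.partition.group_labels)


def test_empty_group_rejected(small_abundance):
    part = ci.GroupPartition.from_mapping(
        {"s1": "A", "s2": "A", "s3": "A"}
    )
    with pytest.raises(ValidationError, match="at least 2 groups"):
        ci.indval_table(small_abundance, part)


def test_permutation_p_planted_indicator_significant():
    ids, part = groups_from_sizes((8, 8, 9))
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(rng.lognormal(0, 0.3, (25, 1)), index=ids,
                        columns=["planted"])
    vals.loc[part.members("A"), "planted"] += 40.0
    pv = ci.indval_permutation_p(ci.AbundanceMatrix(vals), part,
                                 n_perm=999, seed=1)
    p = pv[(pv["taxon"] == "planted") & (pv["group"] == "A")]["p_value"]
    assert float(p.iloc[0]) <= 0.01


def test_permutation_p_constant_taxon_is_one():
    ids, part = groups_from_sizes((3, 3))
    vals = pd.DataFrame({"flat": 2.0}, index=ids)
    pv = ci.indval_permutation_p(ci.AbundanceMatrix(vals), part,
                                 n_perm=99, seed=0)
    assert (pv["p_value"] == 1.0).all()


def test_permutation_count_minimum_enforced(small_abundance):
    part = ci.GroupPartition.from_mapping({"s1": "A", "s2": "A", "s3": "B"})
    with pytest.raises(ValidationError, match="99"):
        ci.indval_permutation_p(small_abundance, part, n_perm=10)


# ---------------------------------------------------------------------------
# consistency solver


def test_solver_recovers_reference_composition(indicator_reference):
    sol = ci.infer_group_sizes(indicator_reference.abundances,
                               indicator_reference.indvals, 25)
    assert sol.sizes == (6, 11, 8)
    assert sol.max_residual <= 0.25
    assert not sol.ambiguous
    assert sol.consistent
    assert sol.second_best_residual > sol.max_residual + 1.0


def test_solver_exact_on_synthetic_table():
    """A table generated with known sizes and exact arithmetic comes back
    with residual 0 and exact recovery."""
    sizes = (4, 7, 5)
    rng = np.random.default_rng(6)
    ab = pd.DataFrame(rng.uniform(1, 60, (8, 3)).round(2),
                      columns=list("ABC"),
                      index=[f"tax{i}" for i in range(8)])
    presence = pd.DataFrame(
        rng.integers(1, np.array(sizes) + 1, (8, 3)),
        columns=list("ABC"), index=ab.index,
    )
    a = ab.div(ab.sum(axis=1), axis=0)
    iv = 100.0 * a * presence / np.array(sizes)
    sol = ci.infer_group_sizes(ab, iv, sum(sizes))
    assert sol.sizes == sizes
    assert sol.max_residual == pytest.approx(0.0, abs=1e-9)
    got = sol.presence.to_numpy()
    assert np.array_equal(got, presence.to_numpy().astype(float))


def test_solver_degenerate_single_taxon_ambiguous():
    """One taxon with fidelity 1 everywhere cannot identify the sizes."""
    ab = pd.DataFrame({"A": [10.0], "B": [30.0]}, index=["only"])
    a = ab.div(ab.sum(axis=1), axis=0)
    iv = 100.0 * a  # B = 1 in both groups
    sol = ci.infer_group_sizes(ab, iv, 10)
    assert sol.ambiguous


def test_solver_inconsistent_table_flagged(indicator_reference):
    iv = indicator_reference.indvals + 40.0
    sol = ci.infer_group_sizes(indicator_reference.abundances, iv.clip(upper=100), 25)
    assert not sol.consistent


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_indval_bounds_property(seed):
    rng = np.random.default_rng(seed)
    ids, part = groups_from_sizes((3, 4, 3))
    vals = pd.DataFrame(
        rng.lognormal(0, 1, (10, 4)) * (rng.random((10, 4)) > 0.3),
        index=ids, columns=[f"t{j}" for j in range(4)],
    )
    table = ci.indval_table(ci.AbundanceMatrix(vals), part)
    assert ((table["specificity"] >= 0) & (table["specificity"] <= 1)).all()
    assert ((table["fidelity"] >= 0) & (table["fidelity"] <= 1)).all()
    assert ((table["indval"] >= 0) & (table["indval"] <= 100 + 1e-9)).all()
    assert (table["n_sites_present"] <= table["group_size"]).all()
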