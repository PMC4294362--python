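"""Normalization, Mann-Whitney U testing, hit calling and export."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from stromascreen import (
    analyze_screen,
    call_hits,
    export_heatmap,
    make_screen_layout,
    mwu_test,
    normalize_to_controls,
    tabulate_wells,
    validate_layout,
)


def _layout_one_sample(n_targets=1, n_reps=3, n_neg=6, n_pos=0):
    targets = [f"G{i}" for i in range(1, n_targets + 1)]
    return make_screen_layout(["S1"], targets, n_replicates=n_reps,
                              n_neg_ctrl=n_neg, n_pos_ctrl=n_pos)


def _well_results(layout, counts_by_well):
    rows = []
    for well in layout["well_id"]:
        rows.append(
            {
                "well_id": well,
                "n_viable_all": counts_by_well[well],
                "n_dead_all": 0,
                "n_msc": 0,
                "n_artifact": 0,
                "n_objects": counts_by_well[well],
                "fields_analyzed": 9,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tabulation


def test_tabulate_counts_labels_per_well():
    layout = _layout_one_sample(n_targets=0, n_reps=0, n_neg=2)
    wells = list(layout["well_id"])
    labels = {
        wells[0]: ["VIABLE_ALL"] * 3 + ["MSC"] * 2,
        wells[1]: [],
    }
    table = tabulate_wells(labels, layout)
    first = table[table["well_id"] == wells[0]].iloc[0]
    assert first["n_viable_all"] == 3 and first["n_msc"] == 2
    second = table[table["well_id"] == wells[1]].iloc[0]
    assert second[["n_viable_all", "n_dead_all", "n_msc", "n_artifact"]].sum() == 0
    # conservation: per-class counts sum to the number of objects
    assert (
        table[["n_viable_all", "n_dead_all", "n_msc", "n_artifact"]].sum(axis=1)
        == table["n_objects"]
    ).all()


def test_tabulate_rejects_well_missing_from_layout():
    layout = _layout_one_sample(n_targets=0, n_reps=0, n_neg=2)
    with pytest.raises(KeyError, match="UNKNOWN"):
        tabulate_wells({"UNKNOWN": []}, layout)


def test_layout_validation():
    layout = _layout_one_sample()
    validate_layout(layout)  # passes
    with pytest.raises(ValueError, match="NEG_CTRL"):
        validate_layout(layout[layout["role"] != "NEG_CTRL"])
    bad = layout.copy()
    bad.loc[0, "role"] = "WEIRD"
    with pytest.raises(ValueError, match="unknown roles"):
        validate_layout(bad)


# ---------------------------------------------------------------------------
# Mann-Whitney U


def test_identical_multisets_give_p_one():
    assert mwu_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    assert mwu_test([5, 5, 5], [5, 5, 5]) == pytest.approx(1.0)


def test_complete_separation_three_vs_three():
    # 2 extreme assignments out of C(6,3)=20 -> exact two-sided p = 0.1
    assert mwu_test([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)
    assert mwu_test([10, 11, 12], [1, 2, 3]) == pytest.approx(0.1)


def test_empty_group_raises():
    with pytest.raises(ValueError):
        mwu_test([], [1, 2])


@pytest.mark.parametrize(
    "n1,n2",
    [(n1, n2) for total in range(2, 11) for n1 in range(1, total) for n2 in [total - n1]],
)
def test_exact_p_matches_scipy_enumeration(n1, n2):
    rng = np.random.default_rng(n1 * 100 + n2)
    for _ in range(5):
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        expected = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert mwu_test(x, y) == pytest.approx(float(expected), abs=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(0, 10_000), min_size=1, max_size=6),
    st.lists(st.integers(0, 10_000), min_size=1, max_size=6),
)
def test_p_value_always_in_unit_interval(xs, ys):
    p = mwu_test(np.array(xs) + 0.0, np.array(ys) + 0.5)  # half-offset avoids x-y ties
    assert 0.0 < p <= 1.0


# ---------------------------------------------------------------------------
# normalization and hits


def test_survival_ratio_arithmetic():
    layout = _layout_one_sample(n_targets=1, n_reps=3, n_neg=2)
    wells = layout["well_id"].tolist()
    counts = dict(zip(wells, [50, 60, 70, 120, 120]))  # 3 targets then 2 controls
    table = normalize_to_controls(_well_results(layout, counts), layout)
    target = table[table["role"] == "TARGET"].iloc[0]
    assert target["survival"] == pytest.approx(0.5)
    neg = table[table["role"] == "NEG_CTRL"].iloc[0]
    assert neg["survival"] == pytest.approx(1.0)


def test_counts_equal_to_controls_give_survival_one():
    layout = _layout_one_sample(n_targets=1, n_reps=3, n_neg=3)
    counts = {w: 100 for w in layout["well_id"]}
    table = normalize_to_controls(_well_results(layout, counts), layout)
    assert table["survival"].to_numpy() == pytest.approx(np.ones(len(table)))


def test_zero_control_mean_reported_missing_not_infinite():
    layout = _layout_one_sample(n_targets=1, n_reps=2, n_neg=2)
    counts = {w: 0 for w in layout["well_id"]}
    counts[layout["well_id"].iloc[0]] = 10
    table = normalize_to_controls(_well_results(layout, counts), layout)
    assert table["control_zero"].all()
    assert table["survival"].isna().all()


def test_hit_requires_both_significance_and_decrease():
    base = pd.DataFrame(
        {
            "sample_id": ["S1", "S1", "S1"],
            "target_gene": ["A", "B", "C"],
            "role": ["TARGET"] * 3,
            "survival": [0.4, 1.6, 0.4],
            "p_value": [0.03, 0.03, 0.2],
        }
    )
    table, consensus = call_hits(base, alpha=0.05, min_samples=1)
    by_gene = table.set_index("target_gene")
    assert bool(by_gene.loc["A", "hit"])
    assert not by_gene.loc["B", "hit"] and bool(by_gene.loc["B", "increase"])
    assert not by_gene.loc["C", "hit"]
    assert consensus.set_index("target_gene").loc["A", "consensus_hit"]


def test_well_order_permutation_changes_nothing():
    layout = _layout_one_sample(n_targets=2, n_reps=3, n_neg=6)
    rng = np.random.default_rng(0)
    counts = {w: int(rng.poisson(200)) for w in layout["well_id"]}
    results = _well_results(layout, counts)
    a = normalize_to_controls(results, layout)
    shuffled = results.sample(frac=1.0, random_state=3).reset_index(drop=True)
    layout_shuffled = layout.sample(frac=1.0, random_state=4).reset_index(drop=True)
    b = normalize_to_controls(shuffled, layout_shuffled)
    pd.testing.assert_frame_equal(a, b)


def test_analyze_screen_counts_tests_and_flags_toxic_floor():
    layout = make_screen_layout(["S1", "S2"], ["G1", "G2", "G3"], n_pos_ctrl=3)
    rng = np.random.default_rng(5)
    counts = {}
    for rec in layout.itertuples(index=False):
        lam = {"TARGET": 200, "NEG_CTRL": 200, "POS_CTRL": 1}[rec.role]
        counts[rec.well_id] = int(rng.poisson(lam))
    result = analyze_screen(_well_results(layout, counts), layout)
    assert result.summary["n_tests"] == 6  # 2 samples x 3 targets
    pos = result.table[result.table["role"] == "POS_CTRL"]
    assert (pos["survival"] < 0.05).all()
    assert result.matrix.shape[0] == 2


def test_benjamini_hochberg_column_is_monotone_with_p():
    layout = make_screen_layout(["S1"], ["G1", "G2", "G3", "G4"])
    rng = np.random.default_rng(7)
    counts = {w: int(rng.poisson(200)) for w in layout["well_id"]}
    result = analyze_screen(_well_results(layout, counts), layout, add_bh=True)
    tgt = result.table[result.table["role"] == "TARGET"].sort_values("p_value")
    qs = tgt["q_value"].to_numpy()
    assert (np.diff(qs) >= -1e-12).all()
    assert (qs >= tgt["p_value"].to_numpy() - 1e-12).all()


def test_heatmap_csv_round_trips_exactly(tmp_path):
    matrix = pd.DataFrame(
        [[1.0, 0.2, 1.6], [0.9, 0.4, np.nan]],
        index=["S1", "S2"],
        columns=["G1", "G2", "G3"],
    )
    png = tmp_path / "heat.png"
    csv = tmp_path / "heat.csv"
    export_heatmap(matrix, png, csv)
    assert png.stat().st_size > 0
    back = pd.read_csv(csv, index_col=0)
    pd.testing.assert_frame_equal(matrix, back)
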