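"""Class assignment and the inclusive/exclusive combination lattice."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (
    CIONA_CLASSES,
    CIONA_EXCLUSIVE,
    CIONA_INCLUSIVE,
    CIONA_TOTAL,
    brute_force_counts,
    make_matrix,
)
from cotransmit.coexpression import (
    ClassProfile,
    ConsistencyError,
    assign_classes,
    binary_expression_matrix,
    combination_counts,
    combination_proportions,
    compare_datasets,
    counts_from_inclusive,
    exclusive_from_inclusive,
    inclusive_from_exclusive,
    merge_profile_classes,
    subset_label,
)
from cotransmit.panels import MarkerGene, MarkerPanelSet, resolve_panels


def profile_from_subsets(subsets, class_names):
    membership = np.array(
        [[c in s for c in class_names] for s in subsets], dtype=bool
    ).reshape(len(subsets), len(class_names))
    return ClassProfile(
        cell_ids=[f"c{i}" for i in range(len(subsets))],
        class_names=list(class_names),
        membership=membership,
    )


class TestAssignClasses:
    def toy(self, values, genes):
        m = make_matrix(values, gene_ids=genes, normalized=values)
        panel = MarkerPanelSet(
            "toy", {"GABA": [MarkerGene("PNPO")], "ACh": [MarkerGene("ChT")]}
        )
        resolved, _ = resolve_panels(panel, m)
        return m, resolved

    def test_direct_threshold(self):
        m, resolved = self.toy([[1.5, 0.3]], ["PNPO", "ChT"])
        prof = assign_classes(m, resolved)
        assert prof.cell_subsets() == [frozenset({"GABA"})]

    def test_or_over_markers(self):
        # any single marker above threshold makes the class positive
        m = make_matrix([[0, 2.0, 0]], gene_ids=["cha-1", "unc-17", "cho-1"],
                        normalized=[[0, 2.0, 0]])
        panel = MarkerPanelSet(
            "worm",
            {"Cholinergic": [MarkerGene("cha-1"), MarkerGene("unc-17"), MarkerGene("cho-1")]},
        )
        resolved, _ = resolve_panels(panel, m)
        prof = assign_classes(m, resolved)
        assert prof.membership.tolist() == [[True]]

    def test_exactly_threshold_is_negative(self):
        m, resolved = self.toy([[1.0, 1.0]], ["PNPO", "ChT"])
        prof = assign_classes(m, resolved, threshold=1.0)
        assert prof.cell_subsets() == [frozenset()]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        vals = rng.random((50, 2)) * 3
        m, resolved = self.toy(vals, ["PNPO", "ChT"])
        prev = None
        for thr in (0.5, 1.0, 1.5, 2.0):
            counts = combination_counts(assign_classes(m, resolved, threshold=thr))
            if prev is not None:
                for s, v in counts.inclusive.items():
                    if s:
                        assert v <= prev.inclusive_count(s)
            prev = counts

    def test_merge_classes_is_union(self):
        prof = profile_from_subsets(
            [frozenset({"Ser"}), frozenset({"Dop"}), frozenset({"ACh"}), frozenset()],
            ["Ser", "Dop", "ACh"],
        )
        merged = merge_profile_classes(prof, {"Aminergic": ["Ser", "Dop"]})
        assert merged.class_names == ["ACh", "Aminergic"]
        assert [s for s in merged.cell_subsets()] == [
            frozenset({"Aminergic"}),
            frozenset({"Aminergic"}),
            frozenset({"ACh"}),
            frozenset(),
        ]


class TestCombinationCounts:
    def test_small_enumeration(self):
        prof = profile_from_subsets(
            [frozenset({"G"}), frozenset({"G", "A"}), frozenset()], ["G", "A"]
        )
        counts = combination_counts(prof)
        assert counts.exclusive == {
            frozenset(): 1,
            frozenset({"G"}): 1,
            frozenset({"G", "A"}): 1,
        }
        assert counts.inclusive_count({"G"}) == 2
        assert counts.inclusive_count({"A"}) == 1
        assert counts.inclusive_count(()) == 3

    def test_all_cells_empty(self):
        prof = profile_from_subsets([frozenset()] * 7, ["G", "A"])
        counts = combination_counts(prof)
        assert counts.exclusive[frozenset()] == 7
        assert all(v == 0 for s, v in counts.inclusive.items() if s)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        classes = list("WXYZ")
        prof = ClassProfile(
            cell_ids=[f"c{i}" for i in range(200)],
            class_names=classes,
            membership=rng.random((200, 4)) < 0.3,
        )
        counts = combination_counts(prof)
        excl, incl = brute_force_counts(prof.cell_subsets(), classes)
        for s, v in excl.items():
            assert counts.exclusive_count(s) == v
        for s, v in incl.items():
            assert counts.inclusive_count(s) == v

    def test_conservation(self):
        rng = np.random.default_rng(9)
        prof = ClassProfile(
            cell_ids=[f"c{i}" for i in range(333)],
            class_names=list("ABC"),
            membership=rng.random((333, 3)) < 0.5,
        )
        counts = combination_counts(prof)
        assert sum(counts.exclusive.values()) == 333

    def test_order_invariance(self):
        rng = np.random.default_rng(11)
        membership = rng.random((60, 3)) < 0.4
        classes = ["G", "A", "V"]
        prof = ClassProfile([f"c{i}" for i in range(60)], classes, membership)
        perm = [2, 0, 1]
        prof_p = ClassProfile(
            [f"c{i}" for i in range(60)],
            [classes[i] for i in perm],
            membership[:, perm],
        )
        a = combination_counts(prof)
        b = combination_counts(prof_p)
        assert a.exclusive == b.exclusive and a.inclusive == b.inclusive


class TestTransforms:
    def test_ciona_worked_example(self, ciona_inclusive):
        excl = exclusive_from_inclusive(ciona_inclusive, CIONA_CLASSES, total_cells=CIONA_TOTAL)
        assert excl == CIONA_EXCLUSIVE
        union = sum(v for s, v in excl.items() if s)
        assert union == 514
        assert excl[frozenset()] == 130

    def test_ciona_without_total_omits_empty_set(self, ciona_inclusive):
        excl = exclusive_from_inclusive(ciona_inclusive, CIONA_CLASSES)
        assert frozenset() not in excl
        assert excl[frozenset({"Glutamatergic"})] == 1

    def test_single_class_exclusive_equals_inclusive(self):
        excl = exclusive_from_inclusive({frozenset({"G"}): 12}, ["G"])
        assert excl == {frozenset({"G"}): 12}

    def test_label_keys_accepted(self):
        excl = exclusive_from_inclusive({"G": 5, "A": 2, "G+A": 2}, ["G", "A"])
        assert excl[frozenset({"G"})] == 3

    def test_non_monotone_rejected(self):
        with pytest.raises(ConsistencyError, match="non-monotone"):
            exclusive_from_inclusive({"G": 1, "G+A": 5}, ["G", "A"])

    def test_inconsistent_rejected_naming_subset(self):
        # 19 glutamatergic cells cannot cover 18+2+2 pairwise/triple overlaps
        # under an exclusive reading; as inclusive counts they can (excl{V}=1)
        with pytest.raises(ConsistencyError, match="V"):
            exclusive_from_inclusive(
                {"G": 10, "A": 10, "V": 3, "G+V": 3, "A+V": 3, "G+A": 2, "G+A+V": 2},
                ["G", "A", "V"],
            )

    @pytest.mark.parametrize("seed", range(10))
    def test_round_trip_identity(self, seed):
        rng = np.random.default_rng(seed)
        classes = list("ABCDE")[: rng.integers(1, 6)]
        prof = ClassProfile(
            cell_ids=[f"c{i}" for i in range(100)],
            class_names=classes,
            membership=rng.random((100, len(classes))) < 0.4,
        )
        counts = combination_counts(prof)
        incl = inclusive_from_exclusive(counts.exclusive, classes)
        for s, v in counts.inclusive.items():
            assert incl.get(s, 0) == v
        back = exclusive_from_inclusive(incl, classes, total_cells=100)
        for s, v in counts.exclusive.items():
            assert back.get(s, 0) == v


class TestBinaryExpressionMatrix:
    def test_threshold_table(self):
        m = make_matrix([[2, 0], [0.5, 3]], gene_ids=["GLRA2", "CHRNA3"],
                        normalized=[[2, 0], [0.5, 3]])
        table = binary_expression_matrix(m, ["GLRA2", "CHRNA3"], threshold=1)
        assert table.values.tolist() == [[True, False], [False, True]]

    def test_absent_gene_all_false(self):
        m = make_matrix([[2.0]], gene_ids=["GLRA2"], normalized=[[2.0]])
        with pytest.warns(UserWarning, match="absent"):
            table = binary_expression_matrix(m, ["GLRA2", "DRD3"], threshold=1)
        assert table["DRD3"].tolist() == [False]

    def test_equals_singleton_panel_assignment(self):
        rng = np.random.default_rng(5)
        vals = rng.random((30, 3)) * 2.5
        genes = ["r1", "r2", "r3"]
        m = make_matrix(vals, gene_ids=genes, normalized=vals)
        table = binary_expression_matrix(m, genes, threshold=1)
        panel = MarkerPanelSet("toy", {g: [MarkerGene(g)] for g in genes})
        resolved, _ = resolve_panels(panel, m)
        prof = assign_classes(m, resolved, threshold=1)
        assert (table.values == prof.membership).all()


class TestProportionsAndComparison:
    def test_simple_percentage(self):
        counts = counts_from_inclusive({"G": 5}, ["G"], total_cells=100)
        pct = combination_proportions(counts, which="inclusive")
        assert pct[frozenset({"G"})] == pytest.approx(5.0)

    def test_exclusive_percentages_sum_to_100(self):
        prof = profile_from_subsets(
            [frozenset({"G"})] * 3 + [frozenset()] * 7, ["G"]
        )
        pct = combination_proportions(combination_counts(prof))
        assert sum(pct.values()) == pytest.approx(100.0)

    def test_hydra_dual_fraction(self):
        # 20 of 3,726 nerve-net neurons co-express the GABAergic and
        # cholinergic markers
        counts = counts_from_inclusive(
            {"GABAergic": 529, "Cholinergic": 381, "GABAergic+Cholinergic": 20},
            ["GABAergic", "Cholinergic"],
            total_cells=3726,
        )
        pct = combination_proportions(counts, which="inclusive")
        assert pct[frozenset({"GABAergic", "Cholinergic"})] == pytest.approx(
            100 * 20 / 3726, abs=1e-9
        )
        assert round(pct[frozenset({"GABAergic", "Cholinergic"})], 3) == 0.537

    def test_zero_total_rejected(self):
        empty = combination_counts(profile_from_subsets([], ["G"]))
        with pytest.raises(ValueError, match="zero total"):
            combination_proportions(empty)

    def test_identical_inputs_zero_difference(self):
        counts = counts_from_inclusive({"G": 10, "A": 4, "G+A": 2}, ["G", "A"],
                                       total_cells=100)
        table = compare_datasets(counts, counts, "x", "y")
        assert np.allclose(table["difference"], 0)

    def test_difference_and_ratio(self):
        a = counts_from_inclusive({"G": 40, "A": 30, "G+A": 10}, ["G", "A"], total_cells=100)
        b = counts_from_inclusive({"G": 40, "A": 30, "G+A": 5}, ["G", "A"], total_cells=100)
        table = compare_datasets(a, b, "larva", "adult", which="inclusive")
        row = table[table.subset == "G+A"].iloc[0]
        assert row["difference"] == pytest.approx(5.0)
        assert row["ratio"] == pytest.approx(2.0)

    def test_swapped_arguments_antisymmetric(self):
        a = counts_from_inclusive({"G": 40, "A": 30, "G+A": 10}, ["G", "A"], total_cells=100)
        b = counts_from_inclusive({"G": 35, "A": 20, "G+A": 5}, ["G", "A"], total_cells=200)
        ab = compare_datasets(a, b, "A", "B").set_index("subset")
        ba = compare_datasets(b, a, "B", "A").set_index("subset")
        for s in ab.index:
            assert ab.loc[s, "difference"] == pytest.approx(-ba.loc[s, "difference"])
            ra, rb = ab.loc[s, "ratio"], ba.loc[s, "ratio"]
            if np.isfinite(ra) and ra > 0:
                assert ra == pytest.approx(1.0 / rb)

    def test_disjoint_classes_rejected(self):
        a = counts_from_inclusive({"G": 1}, ["G"], total_cells=10)
        b = counts_from_inclusive({"X": 1}, ["X"], total_cells=10)
        with pytest.raises(ValueError, match="share no classes"):
            compare_datasets(a, b)


@given(st.data())
@settings(max_examples=30, deadline=None, derandomize=True)
def test_moebius_identities_hold_for_random_profiles(data):
    k = data.draw(st.integers(1, 4))
    n = data.draw(st.integers(0, 40))
    classes = [f"C{i}" for i in range(k)]
    bits = data.draw(
        st.lists(st.integers(0, 2**k - 1), min_size=n, max_size=n)
    )
    subsets = [
        frozenset(c for i, c in enumerate(classes) if b >> i & 1) for b in bits
    ]
    prof = profile_from_subsets(subsets, classes) if n else ClassProfile(
        [], classes, np.zeros((0, k), bool)
    )
    counts = combination_counts(prof)
    # identity 1: inclusive(S) = sum over supersets of exclusive
    for s, v in counts.inclusive.items():
        direct = sum(
            ev for t, ev in counts.exclusive.items() if s <= t
        )
        assert v == direct
    # identity 2: conservation
    assert sum(counts.exclusive.values()) == n


def test_upset_plot_written(tmp_path):
    from cotransmit.plotting import plot_upset

    counts = counts_from_inclusive(CIONA_INCLUSIVE, CIONA_CLASSES, total_cells=CIONA_TOTAL)
    out = tmp_path / "upset.png"
    plot_upset(counts, out)
    assert out.stat().st_size > 0


def test_subset_label_uses_panel_order():
    assert subset_label({"A", "G"}, ["G", "A", "V"]) == "G+A"
    assert subset_label(set(), ["G"]) == "(none)"
    with pytest.raises(KeyError):
        subset_label({"Q"}, ["G"])
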