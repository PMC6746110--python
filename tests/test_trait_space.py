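import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from anatidiv.io_formats import TraitSchema, TraitTable, ValidationError
from anatidiv.trait_space import (
    FunctionalDendrogram,
    build_functional_dendrogram,
    gower_similarity,
    to_dissimilarity,
    upgma,
)

from conftest import random_tree


def _table(df: pd.DataFrame, kinds: dict[str, str]) -> TraitTable:
    return TraitTable(df, TraitSchema(kinds=kinds))


class TestGower:
    def test_identical_rows_have_similarity_one(self):
        df = pd.DataFrame({"x": [1.0, 1.0], "b": [1.0, 1.0]}, index=["p", "q"])
        S = gower_similarity(_table(df, {"x": "continuous", "b": "binary"}))
        assert S.loc["p", "q"] == pytest.approx(1.0)

    def test_range_extremes_have_similarity_zero(self):
        df = pd.DataFrame({"x": [0.0, 10.0]}, index=["p", "q"])
        S = gower_similarity(_table(df, {"x": "continuous"}))
        assert S.loc["p", "q"] == pytest.approx(0.0)

    def test_midpoint_plus_matching_binary_gives_075(self):
        # continuous: |5-10|/10 -> similarity 0.5; binary equal -> 1; mean 0.75
        df = pd.DataFrame({"x": [0.0, 5.0, 10.0], "b": [1.0, 1.0, 1.0]},
                          index=["lo", "mid", "hi"])
        S = gower_similarity(_table(df, {"x": "continuous", "b": "binary"}))
        assert S.loc["mid", "hi"] == pytest.approx(0.75)

    def test_zero_range_trait_dropped_with_warning(self):
        df = pd.DataFrame({"x": [3.0, 3.0], "y": [0.0, 1.0]}, index=["p", "q"])
        with pytest.warns(UserWarning, match="zero range"):
            S = gower_similarity(_table(df, {"x": "continuous", "y": "continuous"}))
        assert S.loc["p", "q"] == pytest.approx(0.0)  # only y informs

    def test_missing_values_are_pairwise_deleted(self):
        df = pd.DataFrame({"x": [0.0, np.nan, 10.0], "b": [1.0, 1.0, 0.0]},
                          index=["p", "q", "r"])
        S = gower_similarity(_table(df, {"x": "continuous", "b": "binary"}))
        assert S.loc["p", "q"] == pytest.approx(1.0)   # only the binary counts
        assert S.loc["p", "r"] == pytest.approx(0.0)   # both traits disagree maximally

    def test_pair_without_shared_traits_is_an_error(self):
        df = pd.DataFrame({"x": [1.0, np.nan], "y": [np.nan, 2.0]}, index=["p", "q"])
        with pytest.raises(ValidationError, match="p.*q|q.*p"):
            gower_similarity(_table(df, {"x": "continuous", "y": "continuous"}))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_similarity_is_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        df = pd.DataFrame(
            {"x": rng.normal(size=n), "y": rng.normal(size=n),
             "b": rng.integers(0, 2, n).astype(float)},
            index=[f"s{i}" for i in range(n)],
        )
        S = gower_similarity(_table(df, {"x": "continuous", "y": "continuous", "b": "binary"}))
        v = S.to_numpy()
        assert np.allclose(v, v.T)
        assert (v >= 0).all() and (v <= 1).all()
        assert np.allclose(np.diag(v), 1.0)


class TestDissimilarity:
    @pytest.mark.parametrize("s,d", [(1.0, 0.0), (0.0, 1.0), (0.75, 0.25)])
    def test_complement(self, s, d):
        S = pd.DataFrame([[1.0, s], [s, 1.0]], index=["p", "q"], columns=["p", "q"])
        D = to_dissimilarity(S)
        assert D.loc["p", "q"] == pytest.approx(d)
        assert D.loc["p", "p"] == 0.0


class TestUPGMA:
    def test_two_entities_merge_at_half_height(self):
        D = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]], index=["p", "q"], columns=["p", "q"])
        Z = upgma(D)
        assert Z[0, 2] == pytest.approx(0.4)
        dend = FunctionalDendrogram.from_linkage(Z, ["p", "q"])
        assert dend.tree.branch_sum(["p"]) == pytest.approx(0.2)

    def test_three_entities_average_linkage_by_hand(self):
        # A,B merge at 0.2; C joins at mean(0.6, 0.6) = 0.6
        D = pd.DataFrame(
            [[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        Z = upgma(D)
        assert Z[0, 2] == pytest.approx(0.2)
        assert Z[1, 2] == pytest.approx(0.6)
        dend = FunctionalDendrogram.from_linkage(Z, list("ABC"))
        C = dend.cophenetic()
        assert C.loc["A", "B"] == pytest.approx(0.2)
        assert C.loc["A", "C"] == pytest.approx(0.6)

    def test_equidistant_triple_tie_broken_lexicographically(self):
        D = pd.DataFrame(0.5 * (1 - np.eye(3)), index=list("CAB"), columns=list("CAB"))
        Z = upgma(D)
        # A and B (lexicographically smallest pair) merge first
        first = {int(Z[0, 0]), int(Z[0, 1])}
        labels = list("CAB")
        assert {labels[i] for i in first} == {"A", "B"}

    def test_no_height_inversions(self):
        rng = np.random.default_rng(3)
        n = 12
        M = rng.uniform(0.1, 1.0, (n, n))
        D = pd.DataFrame((M + M.T) / 2, index=[f"s{i}" for i in range(n)],
                         columns=[f"s{i}" for i in range(n)])
        np.fill_diagonal(D.values, 0.0)
        Z = upgma(D)
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_reconstructs_ultrametric_matrix_exactly(self):
        rng = np.random.default_rng(7)
        tree = random_tree(rng, 10)
        # make it ultrametric by using cophenetic distances of a UPGMA tree
        M = rng.uniform(0.1, 1.0, (10, 10))
        D0 = pd.DataFrame((M + M.T) / 2, index=tree.tip_labels, columns=tree.tip_labels)
        np.fill_diagonal(D0.values, 0.0)
        dend = FunctionalDendrogram.from_linkage(upgma(D0), list(D0.index))
        DU = dend.cophenetic()  # ultrametric by construction
        dend2 = FunctionalDendrogram.from_linkage(upgma(DU), list(DU.index))
        assert np.abs(dend2.cophenetic().to_numpy() - DU.to_numpy()).max() < 1e-9

    def test_row_permutation_gives_isomorphic_dendrogram(self):
        rng = np.random.default_rng(11)
        n = 9
        labels = [f"s{i}" for i in range(n)]
        M = rng.uniform(0.1, 1.0, (n, n))
        D = pd.DataFrame((M + M.T) / 2, index=labels, columns=labels)
        np.fill_diagonal(D.values, 0.0)
        C1 = FunctionalDendrogram.from_linkage(upgma(D), labels).cophenetic()
        perm = list(rng.permutation(labels))
        Dp = D.loc[perm, perm]
        C2 = FunctionalDendrogram.from_linkage(upgma(Dp), perm).cophenetic()
        C2 = C2.loc[labels, labels]
        assert np.abs(C1.to_numpy() - C2.to_numpy()).max() < 1e-12

    def test_agrees_with_scipy_average_linkage(self):
        """Independent cross-check against scipy on a tie-free matrix."""
        from scipy.cluster.hierarchy import average, cophenet
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(13)
        n = 15
        M = rng.uniform(0.1, 1.0, (n, n))
        D = pd.DataFrame((M + M.T) / 2, index=[f"s{i}" for i in range(n)],
                         columns=[f"s{i}" for i in range(n)])
        np.fill_diagonal(D.values, 0.0)
        ours = FunctionalDendrogram.from_linkage(upgma(D), list(D.index)).cophenetic()
        theirs = squareform(cophenet(average(squareform(D.to_numpy()))))
        assert np.abs(ours.to_numpy() - theirs).max() < 1e-9


def test_dendrogram_is_ultrametric(pool60):
    _, _, dendro = pool60
    depths = [dendro.tree.branch_sum([sp]) for sp in dendro.labels]
    assert max(depths) - min(depths) < 1e-9


def test_cophenetic_equals_merge_height_of_lca(small_trait_table):
    dend = build_functional_dendrogram(small_trait_table)
    C = dend.cophenetic()
    for a in dend.labels:
        for b in dend.labels:
            if a == b:
                continue
            # tip-to-tip path length through the tree equals cophenetic entry
            path = dend.tree.branch_sum([a, b], "mrca")
            assert path == pytest.approx(C.loc[a, b], abs=1e-9)
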