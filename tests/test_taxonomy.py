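"""Phenotype encoding, Pearson similarity, UPGMA clustering and DDH
relative re-association values."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

import cghtax as cx

TAIWANENSIS = ["BL263", "BL301", "BL302", "BL303", "BL304"]


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_upgma(sim: pd.DataFrame) -> dict[frozenset, float]:
    """Naive UPGMA recomputing every cluster-pair similarity from the leaf
    matrix at each step (the mean over all cross leaf pairs).  Returns the
    height of every internal node keyed by its leaf set."""
    leaves = list(sim.index)
    clusters = [frozenset([l]) for l in leaves]
    heights = {}
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            s = np.mean([sim.loc[x, y] for x in a for y in b])
            rep = tuple(sorted((min(a), min(b))))
            cand = (-s, rep)
            if best is None or cand < best:
                best, pair, height = cand, (a, b), s
        a, b = pair
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
        heights[a | b] = height
    return heights


def tree_heights(tree) -> dict[frozenset, float]:
    return {frozenset(n.leaves()): n.height for n in tree.walk() if not n.is_leaf}


def random_similarity(n, rng):
    vals = rng.uniform(-50, 99, size=(n, n))
    sim = (vals + vals.T) / 2
    np.fill_diagonal(sim, 100.0)
    names = [f"s{i}" for i in range(n)]
    return pd.DataFrame(sim, index=names, columns=names)


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

class TestEncodePhenotypes:
    def test_packaged_table_cells(self):
        table = cx.load_phenotype_table()
        enc = cx.encode_phenotypes(table)
        assert enc.at["BL263", "Aesculin"] == 1.0
        assert enc.at["BL304", "Galactose"] == 0.5
        assert enc.at["BL263", "Salicin"] == 0.0

    def test_packaged_table_shape(self):
        table = cx.load_phenotype_table()
        assert table.shape == (26, 29)

    def test_all_negative_column_is_zero_vector(self):
        table = pd.DataFrame({"c0": ["-", "-"], "c1": ["+", "-"]}, index=["a", "b"])
        enc = cx.encode_phenotypes(table)
        assert (enc["c0"] == 0.0).all()

    def test_unknown_symbol_names_the_cell(self):
        table = pd.DataFrame({"c0": ["+", "?"]}, index=["a", "b"])
        with pytest.raises(ValueError, match="'b'.*'c0'"):
            cx.encode_phenotypes(table)

    def test_alternative_encodings(self):
        table = pd.DataFrame({"c0": ["d", "+"]}, index=["a", "b"])
        assert cx.encode_phenotypes(table, "negative").at["a", "c0"] == 0.0
        assert cx.encode_phenotypes(table, "positive").at["a", "c0"] == 1.0


class TestPearsonSimilarity:
    def test_identical_vectors_give_100(self):
        m = pd.DataFrame([[1.0, 0.0, 0.5], [1.0, 0.0, 0.5]], index=["a", "b"])
        sim = cx.pearson_similarity(m)
        assert sim.at["a", "b"] == pytest.approx(100.0)

    def test_binary_complement_gives_minus_100(self):
        m = pd.DataFrame([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0]], index=["a", "b"])
        sim = cx.pearson_similarity(m)
        assert sim.at["a", "b"] == pytest.approx(-100.0)

    def test_zero_variance_vector_gets_zero_with_warning(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 0.5]], index=["flat", "b"])
        with pytest.warns(UserWarning, match="flat"):
            sim = cx.pearson_similarity(m)
        assert sim.at["flat", "b"] == 0.0
        assert sim.at["flat", "flat"] == 100.0

    def test_matches_textbook_covariance_formula(self):
        enc = cx.encode_phenotypes(cx.load_phenotype_table())
        sim = cx.pearson_similarity(enc)
        x = enc.loc["BL263"].to_numpy()
        y = enc.loc["BL303"].to_numpy()
        cov = ((x - x.mean()) * (y - y.mean())).mean()
        r = cov / (x.std() * y.std())
        assert sim.at["BL263", "BL303"] == pytest.approx(100 * r, abs=1e-9)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.random((10, 8)), index=[f"s{i}" for i in range(10)])
        sim = cx.pearson_similarity(m)
        np.testing.assert_allclose(sim.to_numpy(), sim.to_numpy().T, atol=1e-12)
        assert (sim.to_numpy() >= -100 - 1e-9).all() and (sim.to_numpy() <= 100 + 1e-9).all()
        assert np.allclose(np.diag(sim), 100.0)


class TestUpgma:
    def test_two_strains(self):
        sim = pd.DataFrame([[100.0, 40.0], [40.0, 100.0]],
                           index=["a", "b"], columns=["a", "b"])
        tree = cx.upgma_tree(sim)
        assert tree.height == 40.0
        assert sorted(tree.leaves()) == ["a", "b"]

    def test_single_strain_rejected(self):
        sim = pd.DataFrame([[100.0]], index=["a"], columns=["a"])
        with pytest.raises(ValueError):
            cx.upgma_tree(sim)

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            n = int(rng.integers(3, 8))
            sim = random_similarity(n, rng)
            tree = cx.upgma_tree(sim)
            mine = tree_heights(tree)
            oracle = brute_force_upgma(sim)
            assert set(mine) == set(oracle)
            for key in oracle:
                assert mine[key] == pytest.approx(oracle[key], abs=1e-9)

    def test_merge_heights_match_scipy_average_linkage(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            sim = random_similarity(6, rng)
            tree = cx.upgma_tree(sim)
            Z = linkage(squareform(100 - sim.to_numpy(), checks=False), method="average")
            scipy_heights = sorted(100 - Z[:, 2])
            mine = sorted(h for h in tree_heights(tree).values())
            np.testing.assert_allclose(mine, scipy_heights, atol=1e-9)

    def test_heights_monotone_root_to_leaf(self):
        rng = np.random.default_rng(3)
        sim = random_similarity(12, rng)
        tree = cx.upgma_tree(sim)
        for node in tree.walk():
            for child in node.children:
                assert child.height >= node.height - 1e-9

    def test_taiwanensis_phenotype_subcluster(self):
        """The five rat-isolate strains join under one node at >= 30%
        similarity in the phenotype dendrogram."""
        enc = cx.encode_phenotypes(cx.load_phenotype_table())
        tree = cx.upgma_tree(cx.pearson_similarity(enc))
        res = cx.subcluster_similarity(tree, TAIWANENSIS)
        assert res.monophyletic
        assert res.height >= 30.0


class TestSubclusterSimilarity:
    def test_single_strain_is_leaf_height(self):
        sim = pd.DataFrame([[100.0, 40.0], [40.0, 100.0]],
                           index=["a", "b"], columns=["a", "b"])
        tree = cx.upgma_tree(sim)
        assert cx.subcluster_similarity(tree, ["a"]).height == 100.0

    def test_direct_join_height(self):
        sim = pd.DataFrame([[100.0, 55.0], [55.0, 100.0]],
                           index=["a", "b"], columns=["a", "b"])
        tree = cx.upgma_tree(sim)
        res = cx.subcluster_similarity(tree, ["a", "b"])
        assert res.height == 55.0 and res.monophyletic

    def test_non_monophyly_reports_intruders(self):
        names = ["a", "b", "c"]
        sim = pd.DataFrame(
            [[100.0, 80.0, 20.0], [80.0, 100.0, 20.0], [20.0, 20.0, 100.0]],
            index=names, columns=names)
        tree = cx.upgma_tree(sim)
        res = cx.subcluster_similarity(tree, ["a", "c"])
        assert not res.monophyletic
        assert res.intruders == ["b"]

    def test_unknown_strain_rejected(self):
        sim = pd.DataFrame([[100.0, 40.0], [40.0, 100.0]],
                           index=["a", "b"], columns=["a", "b"])
        tree = cx.upgma_tree(sim)
        with pytest.raises(ValueError, match="zz"):
            cx.subcluster_similarity(tree, ["a", "zz"])


class TestDdhRelativeValues:
    def raw_table(self, rows):
        return pd.DataFrame(rows, columns=["probe_strain", "target_strain",
                                           "replicate", "signal"])

    def test_equal_signal_gives_100_plus_minus_0(self):
        raw = self.raw_table([("p", "p", r, 5000.0) for r in range(3)]
                             + [("p", "t", r, 5000.0) for r in range(3)])
        mean, sd = cx.ddh_relative_values(raw)
        assert mean.at["t", "p"] == pytest.approx(100.0)
        assert sd.at["t", "p"] == pytest.approx(0.0)

    def test_half_signal_gives_50(self):
        raw = self.raw_table([("p", "p", 0, 8000.0), ("p", "t", 0, 4000.0)])
        mean, _ = cx.ddh_relative_values(raw)
        assert mean.at["t", "p"] == pytest.approx(50.0)

    def test_self_diagonal_exactly_100_for_any_input(self):
        _, raw = cx.generate_fixture_tables(seed=11)
        mean, sd = cx.ddh_relative_values(raw)
        for strain in raw["probe_strain"].unique():
            assert mean.at[strain, strain] == 100.0
            assert math.isnan(sd.at[strain, strain])

    def test_values_above_100_are_legal(self):
        raw = self.raw_table([("p", "p", 0, 4000.0), ("p", "t", 0, 4300.0)])
        mean, _ = cx.ddh_relative_values(raw)
        assert mean.at["t", "p"] == pytest.approx(107.5)

    def test_zero_self_signal_rejected(self):
        raw = self.raw_table([("p", "p", 0, 0.0), ("p", "t", 0, 100.0)])
        with pytest.raises(ValueError, match="self"):
            cx.ddh_relative_values(raw)

    def test_packaged_table_semantics(self):
        mean, sd = cx.load_ddh_table()
        assert mean.shape == (26, 6)
        # self cells are exactly 100 with SD omitted
        assert mean.at["taiwanensis_BL263", "taiwanensis_BL263"] == 100.0
        assert math.isnan(sd.at["taiwanensis_BL263", "taiwanensis_BL263"])
        # relative values above 100 occur (intra-species, non-type strain)
        assert mean.at["intestinalis_BL260", "intestinalis_DSMZ6629T"] == pytest.approx(107.55)
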