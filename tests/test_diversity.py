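"""Hill-number diversities and turnover against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from magdyn.diversity import (
    beta_partition,
    gower_distance,
    hill_func,
    hill_neutral,
    hill_phylo,
    sorensen_turnover,
    turnover_distance_matrix,
    turnover_series,
)
from magdyn.io import Phylogeny

from conftest import random_simplex


def func_hill_oracle(p, d, q=1.0):
    """Direct double-sum evaluation of the attribute-diversity formula."""
    p = np.asarray(p, float)
    d = np.asarray(d, float)
    keep = p > 0
    p, d = p[keep], d[np.ix_(keep, keep)]
    Q = sum(d[i, j] * p[i] * p[j] for i in range(len(p)) for j in range(len(p)))
    if abs(q - 1.0) < 1e-10:
        s = sum(
            (d[i, j] / Q) * p[i] * p[j] * np.log(p[i] * p[j])
            for i in range(len(p))
            for j in range(len(p))
            if d[i, j] > 0
        )
        return np.exp(-0.5 * s)
    s = sum(
        (d[i, j] / Q) * (p[i] * p[j]) ** q for i in range(len(p)) for j in range(len(p))
    )
    return s ** (1 / (2 * (1 - q)))


class TestNeutral:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.5, 0.5], 2.0),
            (np.full(10, 0.1), 10.0),
            ([0.7, 0.2, 0.1], 2.229591873920416),  # exp of hand-computed Shannon 0.80182
        ],
    )
    def test_q1_values(self, p, expected):
        assert hill_neutral(p, 1.0) == pytest.approx(expected, abs=1e-9)

    def test_exp_shannon_identity_on_random_simplexes(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = random_simplex(rng, rng.integers(2, 30))
            shannon = -(p[p > 0] * np.log(p[p > 0])).sum()
            assert abs(hill_neutral(p, 1.0) - np.exp(shannon)) < 1e-12

    def test_other_orders(self):
        p = np.array([0.5, 0.25, 0.25])
        assert hill_neutral(p, 0.0) == pytest.approx(3.0)
        assert hill_neutral(p, 2.0) == pytest.approx(1.0 / np.sum(p**2))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            hill_neutral(np.zeros(3))


class TestPhylo:
    def test_star_tree_reduces_to_neutral(self, star_tree):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p = random_simplex(rng, 4)
            assert hill_phylo(p, star_tree, mag_ids=["A", "B", "C", "D"]) == pytest.approx(
                hill_neutral(p), abs=1e-9
            )

    def test_single_lineage(self):
        t = Phylogeny.from_newick("(A:1,B:1);")
        assert hill_phylo([1.0, 0.0], t, mag_ids=["A", "B"]) == pytest.approx(1.0)

    def test_balanced_tree_against_branch_enumeration(self, balanced_tree):
        # ((A:1,B:1):1,(C:1,D:1):1), uniform p: tips a=1/4 L=1, internals a=1/2 L=1
        # T = 4*(1/4) + 2*(1/2) = 2; value = exp(-(1/2)(ln 1/4 + ln 1/2)) = 2^1.5
        p = np.full(4, 0.25)
        value = hill_phylo(p, balanced_tree, mag_ids=["A", "B", "C", "D"])
        assert value == pytest.approx(2**1.5, abs=1e-12)

    def test_unnormalized_is_t_times_normalized(self, balanced_tree):
        p = np.array([0.4, 0.3, 0.2, 0.1])
        ids = ["A", "B", "C", "D"]
        lengths, incidence = balanced_tree.branch_arrays(ids)
        T = lengths @ (incidence @ p)
        assert hill_phylo(p, balanced_tree, mag_ids=ids, normalized=False) == pytest.approx(
            T * hill_phylo(p, balanced_tree, mag_ids=ids)
        )


class TestGower:
    def test_identical_rows_zero(self):
        t = pd.DataFrame([[0.2, 0.9], [0.2, 0.9], [0.8, 0.1]], index=list("abc"))
        d = gower_distance(t)
        assert d.loc["a", "b"] == 0.0

    def test_opposite_extremes_one(self):
        t = pd.DataFrame([[0.0, 0.0], [1.0, 1.0]], index=["lo", "hi"])
        assert gower_distance(t).loc["lo", "hi"] == pytest.approx(1.0)

    def test_hand_computed_scaled_differences(self):
        # anchor rows fix both trait ranges to 1
        t = pd.DataFrame(
            [[0.2, 0.8], [0.4, 0.4], [0.0, 0.0], [1.0, 1.0]], index=list("xyab")
        )
        assert gower_distance(t).loc["x", "y"] == pytest.approx(0.3)

    def test_constant_trait_excluded(self):
        t = pd.DataFrame([[0.1, 0.5], [0.9, 0.5]], index=["a", "b"])
        assert gower_distance(t).loc["a", "b"] == pytest.approx(1.0)

    def test_all_constant_rejected(self):
        t = pd.DataFrame([[0.5, 0.5], [0.5, 0.5]])
        with pytest.raises(ValueError, match="constant"):
            gower_distance(t)


class TestFunctional:
    def test_two_equally_distinct_mags(self):
        d = np.array([[0.0, 0.37], [0.37, 0.0]])
        assert hill_func([0.5, 0.5], d) == pytest.approx(2.0, abs=1e-12)

    def test_uniform_equidistant_community(self):
        for s in (3, 5, 8):
            d = np.full((s, s), 0.6)
            np.fill_diagonal(d, 0.0)
            assert hill_func(np.full(s, 1 / s), d) == pytest.approx(s, abs=1e-9)

    def test_toy_triple_against_double_sum(self):
        d = np.array([[0, 0.4, 0.8], [0.4, 0, 0.6], [0.8, 0.6, 0]])
        p = [0.5, 0.3, 0.2]
        assert hill_func(p, d) == pytest.approx(3.1093779978596032, abs=1e-12)
        assert hill_func(p, d) == pytest.approx(func_hill_oracle(p, d), abs=1e-12)

    def test_matches_oracle_on_random_draws(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            s = rng.integers(2, 9)
            p = random_simplex(rng, s)
            d = rng.uniform(0.05, 1.0, size=(s, s))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            for q in (1.0, 0.5, 2.0):
                assert hill_func(p, d, q) == pytest.approx(
                    func_hill_oracle(p, d, q), abs=1e-9
                )

    def test_functionally_uniform_community_rejected(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValueError, match="uniform"):
            hill_func([0.5, 0.5], d)


class TestPartition:
    def test_identical_samples_beta_one_all_components(self, balanced_tree):
        p = np.array([0.4, 0.3, 0.2, 0.1])
        d = np.array(
            [[0, 0.2, 0.7, 0.9], [0.2, 0, 0.5, 0.6], [0.7, 0.5, 0, 0.3], [0.9, 0.6, 0.3, 0]]
        )
        ids = ["A", "B", "C", "D"]
        for component, kw in [
            ("neutral", {}),
            ("phylogenetic", {"tree": balanced_tree}),
            ("functional", {"distances": d}),
        ]:
            alpha, gamma, beta = beta_partition(
                np.vstack([p, p, p]), component, mag_ids=ids, **kw
            )
            assert beta == pytest.approx(1.0, abs=1e-9)
            assert alpha == pytest.approx(gamma, rel=1e-9)

    def test_replication_invariance_neutral(self):
        rng = np.random.default_rng(3)
        p = random_simplex(rng, 6)
        alpha, _, beta = beta_partition(np.vstack([p, p]), "neutral")
        assert alpha == pytest.approx(hill_neutral(p), rel=1e-12)
        assert beta == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_uniform_pair_neutral_beta_two(self):
        x = np.array([0.5, 0.5, 0.0, 0.0])
        y = np.array([0.0, 0.0, 0.5, 0.5])
        _, _, beta = beta_partition(np.vstack([x, y]), "neutral")
        assert beta == pytest.approx(2.0, abs=1e-12)

    def test_overlapping_pair_matches_pooled_vs_mean_oracle(self):
        x = np.array([0.6, 0.4, 0.0])
        y = np.array([0.2, 0.3, 0.5])
        alpha, gamma, beta = beta_partition(np.vstack([x, y]), "neutral")
        assert gamma == pytest.approx(2.94623365229395, abs=1e-10)
        assert alpha == pytest.approx(2.342766135781613, abs=1e-10)
        assert beta == pytest.approx(1.2575876043688001, abs=1e-10)

    def test_functional_beta_range_and_identity(self):
        d = np.array([[0, 0.5, 0.9], [0.5, 0, 0.4], [0.9, 0.4, 0]])
        x = np.array([0.8, 0.2, 0.0])
        y = np.array([0.0, 0.3, 0.7])
        _, _, beta = beta_partition(np.vstack([x, y]), "functional", distances=d)
        assert 1.0 <= beta <= 4.0

    def test_mag_order_permutation_invariance(self, balanced_tree):
        rng = np.random.default_rng(4)
        ids = ["A", "B", "C", "D"]
        p1, p2 = random_simplex(rng, 4), random_simplex(rng, 4)
        d = rng.uniform(0.1, 1.0, (4, 4))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ddf = pd.DataFrame(d, index=ids, columns=ids)
        perm = [2, 0, 3, 1]
        pids = [ids[i] for i in perm]
        for component, kw, kwp in [
            ("neutral", {}, {}),
            ("phylogenetic", {"tree": balanced_tree}, {"tree": balanced_tree}),
            ("functional", {"distances": ddf}, {"distances": ddf}),
        ]:
            ref = beta_partition(np.vstack([p1, p2]), component, mag_ids=ids, **kw)
            got = beta_partition(
                np.vstack([p1[perm], p2[perm]]), component, mag_ids=pids, **kwp
            )
            assert got == pytest.approx(ref, rel=1e-9)


class TestTurnover:
    @pytest.mark.parametrize(
        "beta,n,component,expected",
        [
            (1.0, 2, "neutral", 0.0),
            (2.0, 2, "neutral", 1.0),
            (2.5, 2, "functional", 0.5),  # (2.5-1)/(4-1)
            (3.0, 5, "neutral", 0.5),
        ],
    )
    def test_rescaling(self, beta, n, component, expected):
        assert sorensen_turnover(beta, n, component) == pytest.approx(expected)

    def test_out_of_range_beta_rejected(self):
        with pytest.raises(ValueError):
            sorensen_turnover(2.4, 2, "neutral")
        with pytest.raises(ValueError):
            sorensen_turnover(0.9, 2, "neutral")

    def test_linear_normalization_option(self):
        assert sorensen_turnover(
            1.6, 2, "functional", functional_normalization="linear"
        ) == pytest.approx(0.6)

    def test_constant_series_all_zero(self):
        p = np.array([0.25, 0.25, 0.5])
        df = pd.DataFrame([p] * 5, columns=["a", "b", "c"])
        out = turnover_series(df, "neutral")
        assert out["consecutive"] == pytest.approx([0.0] * 4, abs=1e-9)
        assert out["overall"] == pytest.approx(0.0, abs=1e-9)

    def test_alternating_disjoint_pair_is_complete_turnover(self):
        df = pd.DataFrame(
            [[0.5, 0.5, 0, 0], [0, 0, 0.5, 0.5]], columns=list("abcd"), dtype=float
        )
        out = turnover_series(df, "neutral")
        assert out["consecutive"] == pytest.approx([1.0])

    def test_three_point_series_matches_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        rows = [random_simplex(rng, 4) for _ in range(3)]
        df = pd.DataFrame(rows, columns=list("abcd"))
        out = turnover_series(df, "neutral")
        for i, t in enumerate(out["consecutive"]):
            _, _, beta = beta_partition(np.vstack([rows[i], rows[i + 1]]), "neutral")
            assert t == pytest.approx(sorensen_turnover(beta, 2, "neutral"))
        _, _, beta_all = beta_partition(np.vstack(rows), "neutral")
        assert out["overall"] == pytest.approx(sorensen_turnover(beta_all, 3, "neutral"))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_turnover_bounds_symmetry_and_self_zero(self, seed):
        rng = np.random.default_rng(seed)
        s = int(rng.integers(2, 7))
        x, y = random_simplex(rng, s), random_simplex(rng, s)
        _, _, bxy = beta_partition(np.vstack([x, y]), "neutral")
        _, _, byx = beta_partition(np.vstack([y, x]), "neutral")
        t = sorensen_turnover(bxy, 2, "neutral")
        assert 0.0 <= t <= 1.0
        assert t == pytest.approx(sorensen_turnover(byx, 2, "neutral"), abs=1e-12)
        _, _, bxx = beta_partition(np.vstack([x, x]), "neutral")
        assert sorensen_turnover(bxx, 2, "neutral") == pytest.approx(0.0, abs=1e-9)

    def test_distance_matrix_shape_and_extremes(self):
        df = pd.DataFrame(
            [[0.5, 0.5, 0, 0], [0.5, 0.5, 0, 0], [0, 0, 0.5, 0.5]],
            index=["s1", "s2", "s3"],
            columns=list("abcd"),
            dtype=float,
        )
        m = turnover_distance_matrix(df, "neutral")
        assert m.loc["s1", "s2"] == pytest.approx(0.0, abs=1e-9)
        assert m.loc["s1", "s3"] == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(m, m.T)
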