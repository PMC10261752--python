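import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chisquare

from symbionet import (
    BipartiteNetwork,
    r2dtable_null,
    significance,
    vaznull,
)

from conftest import random_network


class TestVaznull:
    def test_constraints_hold_on_every_draw(self):
        rng = np.random.default_rng(0)
        net = random_network(rng, 8, 5, high=15)
        ens = vaznull(net, 40, seed=1)
        for m in ens.matrices:
            assert m.shape == net.weights.shape
            assert np.count_nonzero(m) == net.n_links
            assert m.sum() == net.total_weight
            assert (m.sum(axis=1) > 0).all() and (m.sum(axis=0) > 0).all()

    def test_single_cell_network_reproduced(self):
        net = BipartiteNetwork(("r",), ("c",), np.array([[7]]))
        ens = vaznull(net, 5, seed=0)
        for m in ens.matrices:
            assert m[0, 0] == 7

    def test_impossible_coverage_errors(self):
        # 3x3 diagonal has 3 links but a 1-link 3x1-style case cannot cover
        net = BipartiteNetwork(
            ("a", "b", "c"), ("x", "y"), np.array([[5, 0], [4, 0], [0, 3]])
        )
        # 3 links >= max(3, 2): fine
        vaznull(net, 2, seed=0)
        bad = BipartiteNetwork(("a",), ("x", "y"), np.array([[2, 1]]))
        ens = vaznull(bad, 2, seed=0)   # 2 links cover 1 row, 2 cols
        assert all(np.count_nonzero(m) == 2 for m in ens.matrices)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(3)
        net = random_network(rng, 6, 4)
        a = vaznull(net, 10, seed=5)
        b = vaznull(net, 10, seed=5)
        for ma, mb in zip(a.matrices, b.matrices):
            np.testing.assert_array_equal(ma, mb)

    def test_marginals_preserved_on_average(self):
        rng = np.random.default_rng(8)
        w = rng.integers(5, 40, size=(5, 4))
        net = BipartiteNetwork.from_weights(
            w, list("abcde"), list("wxyz"))
        ens = vaznull(net, 600, seed=2)
        mats = np.array(ens.matrices)
        mean_rows = mats.sum(axis=2).mean(axis=0)
        mean_cols = mats.sum(axis=1).mean(axis=0)
        assert np.all(np.abs(mean_rows / net.row_totals - 1) < 0.05)
        assert np.all(np.abs(mean_cols / net.col_totals - 1) < 0.05)

    def test_non_integer_weights_rejected(self):
        net = BipartiteNetwork(("a",), ("x", "y"), np.array([[1.5, 2.0]]))
        with pytest.raises(ValueError, match="integer"):
            vaznull(net, 2, seed=0)


class TestR2dtable:
    def test_margins_exact_on_every_draw(self):
        rng = np.random.default_rng(1)
        net = random_network(rng, 7, 4, high=20)
        ens = r2dtable_null(net, 50, seed=2)
        for m in ens.matrices:
            np.testing.assert_array_equal(m.sum(axis=1), net.row_totals)
            np.testing.assert_array_equal(m.sum(axis=0), net.col_totals)

    def test_unit_margins_split_evenly(self):
        # margins (1,1)/(1,1): only two tables, each with probability 1/2
        net = BipartiteNetwork(("a", "b"), ("x", "y"), np.array([[1, 0], [0, 1]]))
        ens = r2dtable_null(net, 4000, seed=3)
        diag = sum(int(m[0, 0] == 1) for m in ens.matrices)
        rate = diag / ens.n
        assert abs(rate - 0.5) < 0.03

    def test_cell_mean_matches_hypergeometric_expectation(self):
        rng = np.random.default_rng(4)
        net = random_network(rng, 4, 3, high=15)
        ens = r2dtable_null(net, 2000, seed=5)
        mats = np.array(ens.matrices)
        expected = np.outer(net.row_totals, net.col_totals) / net.total_weight
        assert np.allclose(mats.mean(axis=0), expected, rtol=0.08, atol=0.3)

    def test_non_integer_weights_instruct_rarefaction(self):
        net = BipartiteNetwork(("a",), ("x", "y"), np.array([[0.5, 1.0]]))
        with pytest.raises(ValueError, match="rarefy"):
            r2dtable_null(net, 2, seed=0)


class TestSignificance:
    def test_constant_nulls_give_p_one_and_z_zero(self):
        res = significance(2.0, [2.0] * 50, tail="two-sided")
        assert res.p == 1.0
        assert np.isnan(res.z)  # zero spread: z undefined

    def test_add_one_convention_lower_tail(self):
        nulls = list(range(1, 100))     # 99 nulls, all above observed
        res = significance(0.0, nulls, tail="lower")
        assert res.p == pytest.approx(1 / 100)

    def test_z_matches_direct_arithmetic(self):
        nulls = [3.0, 5.0, 7.0, 9.0]
        res = significance(10.0, nulls, tail="upper")
        mean, sd = np.mean(nulls), np.std(nulls, ddof=1)
        assert res.z == pytest.approx((10 - mean) / sd)
        assert res.ci95[0] <= res.ci95[1]

    def test_empty_nulls_error(self):
        with pytest.raises(ValueError):
            significance(1.0, [])

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=40),
           st.floats(-50, 50),
           st.sampled_from(["lower", "upper", "two-sided"]))
    @settings(max_examples=50, deadline=None)
    def test_p_always_in_unit_interval(self, nulls, obs, tail):
        res = significance(obs, nulls, tail=tail)
        assert 0 < res.p <= 1


def test_ensemble_serialization_round_trips(tmp_path):
    rng = np.random.default_rng(10)
    net = random_network(rng, 4, 3)
    ens = vaznull(net, 3, seed=1)
    ens.to_dir(tmp_path)
    import json
    manifest = json.loads((tmp_path / "manifest.json").read_text())
    assert manifest["method"] == "vaznull" and manifest["n"] == 3
    first = (tmp_path / "null_0000.tsv").read_text().splitlines()
    assert first[0].split("\t")[1:] == list(ens.col_ids)
    assert len(first) == 1 + len(ens.row_ids)
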