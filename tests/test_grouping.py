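import numpy as np
import pandas as pd
import pytest

from symbionet import (
    TissuePartition,
    aicc,
    akaike_weights,
    compare_partitions,
    conditional_modes,
    enumerate_partitions,
    evidence_ratio,
    fit_zi_glmm,
    likelihood_ratio_test,
    long_counts,
)
from symbionet.grouping import _pivot
from symbionet.zinb import (
    _Block,
    _grad_hess,
    _penalized_obj,
    fit_zinb_glmm_arrays,
    simulate_zinb_dataset,
)
import symbionet.zinb as zinb_mod


def glmm_frame(Y, gidx, offset, groups):
    """Assemble a LongCounts frame from pivoted arrays."""
    T, S = Y.shape
    rows = []
    for s in range(S):
        for t in range(T):
            rows.append((f"s{s}", "site0", groups[gidx[s]], f"t{t}",
                         Y[t, s], offset[s]))
    return pd.DataFrame(rows, columns=[
        "sample_id", "site_id", "tissue", "taxon_id", "count", "offset"])


class TestPartitionEnumeration:
    def test_four_tissues_give_fourteen_models(self):
        parts = enumerate_partitions()
        assert len(parts) == 14
        names = {p.name for p in parts}
        assert "cg-mo" in names and "c-g-m-o" in names

    @pytest.mark.parametrize("n,expected", [(2, 1), (3, 4), (4, 14),
                                            (5, 51), (6, 202)])
    def test_counts_follow_bell_numbers(self, n, expected):
        tissues = [f"tissue_{c}" for c in "abcdef"[:n]]
        parts = enumerate_partitions(tissues)
        assert len(parts) == expected
        assert len({p.name for p in parts}) == expected  # duplicate-free

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            enumerate_partitions(["crop", "crop", "ovary"])

    def test_names_are_canonical_and_parseable(self):
        for part in enumerate_partitions():
            back = TissuePartition.from_name(part.name)
            assert back.groups == part.groups


class TestInformationCriteria:
    def test_aicc_known_value(self):
        assert aicc(0.0, 1, 10) == pytest.approx(2.5)

    def test_aicc_approaches_aic_for_large_n(self):
        aic = -2 * (-100.0) + 2 * 5
        assert aicc(-100.0, 5, 10**7) == pytest.approx(aic, abs=1e-4)

    def test_aicc_requires_enough_observations(self):
        with pytest.raises(ValueError):
            aicc(0.0, 5, 6)

    def test_weights_sum_to_one_and_single_model(self):
        assert akaike_weights([0.0]) == pytest.approx([1.0])
        w = akaike_weights([0.0, 1.3, 2.7, 9.0])
        assert w.sum() == pytest.approx(1.0)
        assert (np.diff(w) < 0).all()

    def test_weight_ratio_identity(self):
        w = akaike_weights([0.0, 3.0])
        assert evidence_ratio(w[0], w[1]) == pytest.approx(np.exp(1.5))
        assert evidence_ratio(0.5, 0.5) == pytest.approx(1.0)
        assert evidence_ratio(0.5, 0.0) == np.inf

    def test_negative_deltas_rejected(self):
        with pytest.raises(ValueError):
            akaike_weights([1.0, 2.0])   # minimum must be 0


class TestFitting:
    @pytest.fixture(scope="class")
    def sim_two_groups(self):
        Y, gidx, off, truth = simulate_zinb_dataset(
            n_taxa=25, groups=["A", "B"], samples_per_group=20,
            beta=[1.0, 1.5], sigma_u=0.8, sigma_v=0.8, theta=2.0,
            zeta0=-1.2, sigma_z=0.5, offset=2.0, seed=10)
        return Y, gidx, off, truth

    def test_grouping_loglik_dominates_null(self, sim_two_groups):
        Y, gidx, off, _ = sim_two_groups
        full = fit_zinb_glmm_arrays(Y, off, gidx, 2, ("A", "B"))
        null = fit_zinb_glmm_arrays(Y, off, None, 0)
        assert full.loglik >= null.loglik - 1e-6
        assert full.k == 7 and null.k == 5

    def test_interaction_variance_shrinks_without_structure(self):
        Y, gidx, off, _ = simulate_zinb_dataset(
            n_taxa=25, groups=["A", "B"], samples_per_group=20,
            beta=[1.2, 1.2], sigma_u=0.8, sigma_v=0.0, theta=2.0,
            zeta0=-1.2, sigma_z=0.5, offset=2.0, seed=11)
        fit = fit_zinb_glmm_arrays(Y, off, gidx, 2, ("A", "B"))
        assert fit.sigma_v2 < 0.05
        assert np.abs(fit.modes_v).max() < 0.15   # modes shrink toward 0

    def test_no_zero_inflation_recovered_as_small(self):
        Y, gidx, off, _ = simulate_zinb_dataset(
            n_taxa=25, groups=["A", "B"], samples_per_group=20,
            beta=[1.5, 2.0], sigma_u=0.8, sigma_v=0.5, theta=3.0,
            zeta0=-10.0, sigma_z=0.01, offset=2.0, seed=12)
        fit = fit_zinb_glmm_arrays(Y, off, gidx, 2, ("A", "B"))
        assert fit.zero_inflation_mean < 0.05

    def test_enriched_taxon_has_largest_conditional_mode(self, sim_two_groups):
        Y, gidx, off, truth = sim_two_groups
        fit = fit_zinb_glmm_arrays(Y, off, gidx, 2, ("A", "B"),
                                   taxon_ids=[f"t{i}" for i in range(25)])
        modes = conditional_modes(fit)
        # the taxon intercept absorbs each taxon's average response, so the
        # recoverable signal is the within-taxon contrast across groups
        v_contrast = truth["v"] - truth["v"].mean(axis=1, keepdims=True)
        for g in range(2):
            top_true = int(np.argmax(v_contrast[:, g]))
            rank = modes.iloc[:, g].rank(ascending=False)[f"t{top_true}"]
            assert rank <= 3
            assert modes.iloc[:, g][f"t{top_true}"] > 0
        m_contrast = fit.modes_v - fit.modes_v.mean(axis=1, keepdims=True)
        corr = np.corrcoef(m_contrast.ravel(), v_contrast.ravel())[0, 1]
        assert corr > 0.6

    def test_conditional_modes_require_interaction(self, sim_two_groups):
        Y, gidx, off, _ = sim_two_groups
        null = fit_zinb_glmm_arrays(Y, off, None, 0)
        with pytest.raises(ValueError, match="null"):
            conditional_modes(null)

    def test_likelihood_ratio_test_arithmetic(self, sim_two_groups):
        Y, gidx, off, _ = sim_two_groups
        full = fit_zinb_glmm_arrays(Y, off, gidx, 2, ("A", "B"))
        null = fit_zinb_glmm_arrays(Y, off, None, 0)
        stat, df, p = likelihood_ratio_test(full, null)
        assert stat == pytest.approx(2 * (full.loglik - null.loglik))
        assert df == 2
        assert p < 0.01    # strong planted tissue structure
        stat0, _, p0 = likelihood_ratio_test(full, null)
        with pytest.raises(ValueError):
            likelihood_ratio_test(null, full)

    def test_poisson_family_supported(self):
        Y, gidx, off, _ = simulate_zinb_dataset(
            n_taxa=15, groups=["A", "B"], samples_per_group=12,
            beta=[1.0, 1.5], sigma_u=0.5, sigma_v=0.3, theta=np.inf,
            zeta0=-1.5, sigma_z=0.3, offset=1.0, seed=13)
        fit = fit_zinb_glmm_arrays(Y, off, gidx, 2, ("A", "B"),
                                   family="poisson")
        assert np.isinf(fit.theta)
        assert fit.k == 6   # no dispersion parameter


class TestKernelsAgainstReference:
    def test_compiled_and_numpy_paths_agree(self):
        if not zinb_mod._HAVE_KERNELS:
            # reference path is the implementation; nothing to compare
            return
        rng = np.random.default_rng(3)
        Y = rng.poisson(4.0, size=(12, 18))
        Y[rng.random(Y.shape) < 0.35] = 0
        gidx = rng.integers(0, 3, 18)
        blk = _Block.build(Y, rng.normal(0, 1, 18), gidx, 3)
        B = rng.normal(0, 0.7, (12, 5))
        for family, theta in [("nbinom2", 1.7), ("poisson", np.inf)]:
            args = (np.array([0.4, 0.9, 1.4]), theta, 0.7, 0.5, -0.8, 0.4,
                    family)
            o1 = _penalized_obj(blk, B, *args)
            g1, h1 = _grad_hess(blk, B, *args)
            zinb_mod._HAVE_KERNELS = False
            try:
                o2 = _penalized_obj(blk, B, *args)
                g2, h2 = _grad_hess(blk, B, *args)
            finally:
                zinb_mod._HAVE_KERNELS = True
            np.testing.assert_allclose(o1, o2, rtol=0, atol=1e-10)
            np.testing.assert_allclose(g1, g2, rtol=0, atol=1e-10)
            np.testing.assert_allclose(h1, h2, rtol=0, atol=1e-10)


class TestComparePartitions:
    def test_planted_two_group_structure_ranked_first(self):
        Y, gidx, off, _ = simulate_zinb_dataset(
            n_taxa=30, groups=["cg", "mo"], samples_per_group=20,
            beta=[1.0, 1.0], sigma_u=0.8, sigma_v=1.0, theta=2.0,
            zeta0=-1.2, sigma_z=0.5, offset=2.0, seed=20)
        # expand the 2 planted groups onto the 4 tissues
        tissue_of = {0: ["crop", "midgut"], 1: ["malpighian_tubule", "ovary"]}
        tissues = []
        for s, g in enumerate(gidx):
            tissues.append(tissue_of[g][s % 2])
        frame = glmm_frame(Y, np.arange(len(gidx)) * 0, off, ["x"])
        frame["tissue"] = [tissues[int(s[1:])] for s in frame["sample_id"]]
        cmp_ = compare_partitions(frame)
        assert cmp_.best_name == "cg-mo"
        table = cmp_.table
        assert table["delta_aicc"].iloc[0] == 0.0
        assert table["weight"].sum() == pytest.approx(1.0)
        assert set(table.columns) >= {"loglik", "k", "aicc", "delta_aicc",
                                      "weight", "band"}
        assert table["band"].iloc[0] == "indistinguishable"
        assert cmp_.table.at["null", "band"] == "poor fit, rejected"

    def test_unstructured_data_keeps_null_competitive(self):
        Y, gidx, off, _ = simulate_zinb_dataset(
            n_taxa=25, groups=["a", "b", "c", "d"], samples_per_group=10,
            beta=[1.3] * 4, sigma_u=0.8, sigma_v=0.0, theta=2.0,
            zeta0=-1.2, sigma_z=0.5, offset=2.0, seed=21)
        tissues = ["crop", "midgut", "malpighian_tubule", "ovary"]
        frame = glmm_frame(Y, gidx, off, tissues)
        cmp_ = compare_partitions(frame)
        assert cmp_.table.at["null", "delta_aicc"] <= 4.5


def test_long_counts_shapes_and_offsets(small_bundle):
    from symbionet import filter_rare, remove_control_taxa, TISSUES
    cm = filter_rare(remove_control_taxa(small_bundle.counts,
                                         small_bundle.metadata))
    meta = small_bundle.metadata.subset(cm.sample_ids)
    tissue_samples = meta.samples_with(*TISSUES)
    sub = cm.select_samples(tissue_samples).drop_empty_taxa()
    data = long_counts(sub, meta.subset(tissue_samples))
    assert len(data) == sub.shape[0] * sub.shape[1]
    one = data[data["sample_id"] == tissue_samples[0]]
    total = sub.data[tissue_samples[0]].sum()
    assert one["offset"].iloc[0] == pytest.approx(np.log(total))
    Y, off, tissue, sids, tids = _pivot(data)
    assert Y.shape == (sub.shape[0], len(tissue_samples))
    np.testing.assert_array_equal(sorted(sids), sorted(tissue_samples))
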