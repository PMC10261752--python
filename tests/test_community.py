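import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from symbionet import (
    CountMatrix,
    SampleMetadata,
    TaxonAnnotation,
    aggregate,
    exclude_wolbachia,
    filter_rare,
    prevalence_table,
    rarefy,
    read_count_table,
    remove_control_taxa,
    richness,
    sharing_table,
    simpson,
    write_count_table,
)
from symbionet.community import (
    CountTableError,
    scheme_env_merged,
    scheme_env_unmerged,
    scheme_tissues_only,
)

from conftest import make_meta


class TestReadWrite:
    def test_round_trip_preserves_counts_and_order(self, tmp_path, tiny_cm):
        path = tmp_path / "counts.tsv"
        write_count_table(tiny_cm, path)
        back = read_count_table(path)
        pd.testing.assert_frame_equal(back.data, tiny_cm.data,
                                      check_names=False)
        # canonical files re-serialize byte-identically
        path2 = tmp_path / "again.tsv"
        write_count_table(back, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_negative_count_names_offending_cell(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("taxon_id\ts1\ns0\t-1\n")
        with pytest.raises(CountTableError, match="s0.*s1|negative"):
            read_count_table(path)

    def test_non_integer_count_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("taxon_id\ts1\ns0\t1.5\n")
        with pytest.raises(CountTableError, match="non-integer"):
            read_count_table(path)

    def test_duplicate_taxon_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("taxon_id\ts1\nt0\t1\nt0\t2\n")
        with pytest.raises(CountTableError, match="duplicate"):
            read_count_table(path)


class TestControlsAndFilters:
    def _with_controls(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 20, size=(10, 5)),
            index=[f"t{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(5)],
        )
        counts.loc[:, "s4"] = 0
        counts.loc["t3", "s4"] = 7          # contaminant
        counts.loc["t8", "s4"] = 1          # contaminant
        meta = make_meta(
            [(f"s{i}", "site1", "crop") for i in range(4)]
            + [("s4", "site1", "negative_control")]
        )
        return CountMatrix(counts), meta

    def test_contaminants_and_controls_dropped(self):
        cm, meta = self._with_controls()
        out = remove_control_taxa(cm, meta)
        assert out.shape[0] == 8
        assert "t3" not in out.taxon_ids and "t8" not in out.taxon_ids
        assert "s4" not in out.sample_ids

    def test_idempotent_and_identity_without_controls(self):
        cm, meta = self._with_controls()
        once = remove_control_taxa(cm, meta)
        twice = remove_control_taxa(once, meta)
        pd.testing.assert_frame_equal(once.data, twice.data)
        # no controls: taxon set unchanged
        no_ctrl = cm.select_samples(["s0", "s1", "s2", "s3"])
        out = remove_control_taxa(no_ctrl, meta)
        assert out.taxon_ids == cm.taxon_ids

    def test_singletons_removed(self):
        cm = CountMatrix(pd.DataFrame(
            {"s1": [1, 2, 0], "s2": [0, 0, 5]}, index=["single", "ok", "ok2"]
        ))
        out = filter_rare(cm, min_total=2, min_prevalence=0.0)
        assert "single" not in out.taxon_ids
        assert out.taxon_ids == ["ok", "ok2"]

    def test_zero_thresholds_are_identity(self, tiny_cm):
        out = filter_rare(tiny_cm, min_total=0, min_prevalence=0.0)
        pd.testing.assert_frame_equal(out.data, tiny_cm.data)

    def test_prevalence_threshold_uses_ceiling(self):
        # 100 samples at 5%: detected in 4 -> removed, in 5 -> kept
        n = 100
        data = pd.DataFrame(
            0, index=["four", "five"], columns=[f"s{i}" for i in range(n)]
        )
        data.iloc[0, :4] = 1
        data.iloc[1, :5] = 1
        out = filter_rare(CountMatrix(data), min_total=2, min_prevalence=0.05)
        assert out.taxon_ids == ["five"]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_filter_rare_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        data = pd.DataFrame(
            rng.integers(0, 4, size=(12, 8)),
            index=[f"t{i}" for i in range(12)],
            columns=[f"s{i}" for i in range(8)],
        )
        cm = CountMatrix(data)
        once = filter_rare(cm)
        twice = filter_rare(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_wolbachia_exclusion(self):
        cm = CountMatrix(pd.DataFrame(
            {"s1": [1, 2, 3, 4, 5]}, index=[f"t{i}" for i in range(5)]
        ))
        ann = TaxonAnnotation(pd.DataFrame({
            "lineage": ["x"] * 3 + ["Wolbachia;wAlbA", "Wolbachia;wAlbB"],
            "is_wolbachia": [False] * 3 + [True, True],
        }, index=[f"t{i}" for i in range(5)]))
        out = exclude_wolbachia(cm, ann)
        assert out.shape[0] == 3
        # no flags -> identity
        ann0 = TaxonAnnotation(ann.data.assign(is_wolbachia=False))
        assert exclude_wolbachia(cm, ann0).taxon_ids == cm.taxon_ids

    def test_missing_annotation_lists_taxa(self):
        cm = CountMatrix(pd.DataFrame({"s1": [1, 2]}, index=["t0", "t1"]))
        ann = TaxonAnnotation(pd.DataFrame(
            {"lineage": ["x"], "is_wolbachia": [False]}, index=["t0"]
        ))
        with pytest.raises(ValueError, match="t1"):
            exclude_wolbachia(cm, ann)


class TestRarefaction:
    def test_columns_sum_to_depth_and_full_sample_unchanged(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame({
            "deep": rng.multinomial(500, np.ones(20) / 20),
            "exact": np.r_[np.full(5, 20), np.zeros(15)].astype(int),
            "shallow": np.r_[np.ones(3), np.zeros(17)].astype(int),
        }, index=[f"t{i}" for i in range(20)])
        cm = CountMatrix(data)
        out = rarefy(cm, depth=100, seed=3)
        assert "shallow" not in out.sample_ids          # dropped, not an error
        assert (out.sample_totals() == 100).all()
        pd.testing.assert_series_equal(
            out.data["exact"], cm.data["exact"], check_names=False
        )

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        cm = CountMatrix(pd.DataFrame(
            {"s": rng.multinomial(1000, np.ones(30) / 30)},
            index=[f"t{i}" for i in range(30)],
        ))
        a = rarefy(cm, 200, seed=9).data
        b = rarefy(cm, 200, seed=9).data
        pd.testing.assert_frame_equal(a, b)

    def test_expected_counts_match_hypergeometric(self):
        # E[count after rarefaction] = depth * count / total
        counts = np.array([50, 30, 15, 5])
        cm = CountMatrix(pd.DataFrame({"s": counts}, index=list("abcd")))
        depth = 40
        acc = np.zeros(4)
        n_rep = 400
        for seed in range(n_rep):
            acc += rarefy(cm, depth, seed=seed).data["s"].to_numpy()
        expected = depth * counts / counts.sum()
        se = 3 * np.sqrt(expected) / np.sqrt(n_rep)   # generous MC band
        assert np.all(np.abs(acc / n_rep - expected) < np.maximum(se, 0.5))

    def test_richness_never_increases(self):
        rng = np.random.default_rng(4)
        for seed in range(5):
            counts = rng.integers(0, 30, size=(25, 3))
            counts[0] += 40
            cm = CountMatrix(pd.DataFrame(
                counts, index=[f"t{i}" for i in range(25)],
                columns=["a", "b", "c"],
            ))
            depth = int(cm.sample_totals().min())
            out = rarefy(cm, max(depth // 2, 1), seed=seed)
            assert (richness(out) <= richness(cm)[out.sample_ids]).all()


class TestAggregation:
    def _cm_meta(self):
        rng = np.random.default_rng(5)
        samples = []
        rows = []
        for site in range(2):
            for sub in ("crop", "midgut", "malpighian_tubule", "ovary",
                        "soil", "water", "plant_nectar"):
                sid = f"site{site}_{sub}"
                samples.append(sid)
                rows.append((sid, f"site{site}", sub))
        data = pd.DataFrame(
            rng.integers(0, 10, size=(15, len(samples))) + 1,
            index=[f"t{i}" for i in range(15)], columns=samples,
        )
        return CountMatrix(data), make_meta(rows)

    def test_merged_scheme_gives_five_categories(self):
        cm, meta = self._cm_meta()
        net = aggregate(cm, meta, scheme_env_merged())
        assert set(net.col_ids) == {
            "crop", "midgut", "malpighian_tubule", "ovary", "environment"
        }

    def test_total_weight_conserved(self):
        cm, meta = self._cm_meta()
        for scheme in (scheme_env_unmerged(), scheme_env_merged()):
            net = aggregate(cm, meta, scheme)
            assert net.total_weight == cm.counts.sum()
        tissues_net = aggregate(cm, meta, scheme_tissues_only())
        tissue_samples = meta.samples_with(
            "crop", "midgut", "malpighian_tubule", "ovary")
        assert tissues_net.total_weight == cm.data[tissue_samples].sum().sum()

    def test_single_sample_categories_identity(self):
        cm, meta = self._cm_meta()
        one_site = [s for s in cm.sample_ids if s.startswith("site0")]
        sub_cm = cm.select_samples(one_site)
        net = aggregate(sub_cm, meta, scheme_env_unmerged())
        for sid in one_site:
            cat = meta.substrate_of(sid)
            j = list(net.col_ids).index(cat)
            np.testing.assert_array_equal(
                net.weights[:, j],
                sub_cm.data[sid].to_numpy()[np.isin(sub_cm.taxon_ids, net.row_ids)],
            )

    def test_unmapped_substrate_errors(self):
        cm, meta = self._cm_meta()
        with pytest.raises(ValueError, match="not mapped"):
            aggregate(cm, meta, {"crop": "crop"})


class TestDiversityAndSharing:
    def test_simpson_known_values(self):
        cm = CountMatrix(pd.DataFrame({
            "equal4": [5, 5, 5, 5],
            "single": [9, 0, 0, 0],
            "mix": [2, 2, 6, 0],
            "empty": [0, 0, 0, 0],
        }, index=list("wxyz")))
        s = simpson(cm)
        assert s["equal4"] == pytest.approx(0.75)
        assert s["single"] == pytest.approx(0.0)
        assert s["mix"] == pytest.approx(0.56)
        assert np.isnan(s["empty"])

    def test_richness_counts_detections(self, tiny_cm):
        r = richness(tiny_cm)
        assert r["s1"] == 2 and r["s2"] == 2

    def test_sharing_proportions_consistent_and_bounded(self):
        rng = np.random.default_rng(6)
        samples, rows = [], []
        for sub in ("crop", "midgut", "soil", "water"):
            for k in range(2):
                sid = f"{sub}{k}"
                samples.append(sid)
                rows.append((sid, "site1", sub))
        data = pd.DataFrame(
            (rng.random((30, len(samples))) < 0.4).astype(int) * 3,
            index=[f"t{i}" for i in range(30)], columns=samples,
        )
        cm = CountMatrix(data)
        meta = make_meta(rows)
        table = sharing_table(cm, meta, cols=("crop", "midgut"),
                              rows=("soil", "water"))
        props = table.proportions
        assert ((props >= 0) & (props <= 1)).all().all()
        # stored proportions equal shared / column totals recomputed
        recomputed = table.shared / table.col_totals
        pd.testing.assert_frame_equal(props, recomputed)

    def test_subset_tissue_shares_everything(self):
        data = pd.DataFrame({
            "crop_s": [3, 2, 0], "soil_s": [1, 1, 1],
        }, index=["t0", "t1", "t2"])
        meta = make_meta([("crop_s", "x", "crop"), ("soil_s", "x", "soil")])
        table = sharing_table(CountMatrix(data), meta,
                              cols=("crop",), rows=("soil",))
        assert table.proportions.at["soil", "crop"] == pytest.approx(1.0)

    def test_empty_tissue_reports_missing(self):
        data = pd.DataFrame({"crop_s": [0, 0], "soil_s": [1, 2]},
                            index=["t0", "t1"])
        meta = make_meta([("crop_s", "x", "crop"), ("soil_s", "x", "soil")])
        table = sharing_table(CountMatrix(data), meta,
                              cols=("crop",), rows=("soil",))
        assert np.isnan(table.proportions.at["soil", "crop"])

    def test_prevalence_rows_normalized(self):
        data = pd.DataFrame({
            "soil_a": [4, 0], "soil_b": [2, 0], "water_a": [1, 0],
        }, index=["everywhere", "nowhere"])
        meta = make_meta([("soil_a", "x", "soil"), ("soil_b", "x", "soil"),
                          ("water_a", "x", "water")])
        out = prevalence_table(CountMatrix(data), meta)
        assert out.loc["everywhere"].sum() == pytest.approx(1.0)
        assert out.loc["everywhere", "soil"] == pytest.approx(2 / 3)
        assert (out.loc["nowhere"] == 0).all()


def test_biom_json_adapter_matches_tsv_reader(tmp_path):
    import json
    from symbionet.community import read_biom_json

    doc = {
        "rows": [{"id": "tA"}, {"id": "tB"}],
        "columns": [{"id": "s1"}, {"id": "s2"}, {"id": "s3"}],
        "matrix_type": "sparse",
        "data": [[0, 0, 4], [1, 2, 7]],
    }
    path = tmp_path / "table.biom"
    path.write_text(json.dumps(doc))
    cm = read_biom_json(path)
    assert cm.shape == (2, 3)
    assert cm.data.at["tA", "s1"] == 4 and cm.data.at["tB", "s3"] == 7
    assert cm.data.to_numpy().sum() == 11
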