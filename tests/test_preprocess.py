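"""Preprocessing chain: zeros, harmonization, imputation, outliers, totals."""

import logging

import numpy as np
import pandas as pd
import pytest

import lipidpipe as lp
from lipidpipe import preprocess as pp
from lipidpipe.containers import validate_annotation
from lipidpipe.synthdata import make_harmonization_fixture

from conftest import harmonize_oracle, make_manifest, outlier_oracle


def _matrix(values, ids=None, cols=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"s{i}" for i in range(values.shape[0])]
    cols = cols or [f"f{j}" for j in range(values.shape[1])]
    return lp.ConcentrationMatrix(pd.DataFrame(values, index=ids, columns=cols))


class TestReplaceZeros:
    def test_zero_becomes_tenth_of_group_minimum(self):
        m = _matrix([[0.0], [2.0], [10.0]])
        man = make_manifest(m.sample_ids)
        out = pp.replace_zeros(m, man)
        assert out.data["f0"].tolist() == [0.2, 2.0, 10.0]

    def test_no_zeros_is_identity(self):
        m = _matrix([[1.0, 3.0], [2.0, 4.0]])
        out = pp.replace_zeros(m, make_manifest(m.sample_ids))
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_all_zero_feature_becomes_missing_with_warning(self, caplog):
        m = _matrix([[0.0, 1.0], [0.0, 2.0], [0.0, 3.0]])
        with caplog.at_level(logging.WARNING):
            out = pp.replace_zeros(m, make_manifest(m.sample_ids))
        assert out.data["f0"].isna().all()
        assert any("all-zero" in r.message for r in caplog.records)

    def test_groups_are_isolated_by_sample_type(self):
        # the zero in the 6m group must use the 6m minimum, not the birth one
        m = _matrix([[0.0], [50.0], [0.0], [2.0]], ids=["a", "b", "c", "d"])
        man = make_manifest(["a", "b", "c", "d"],
                            timepoint=["birth", "birth", "6m", "6m"],
                            matrix=["serum", "serum", "plasma", "plasma"])
        out = pp.replace_zeros(m, man)
        assert out.data.loc["a", "f0"] == pytest.approx(5.0)
        assert out.data.loc["c", "f0"] == pytest.approx(0.2)

    def test_positive_count_preserved_and_minimum_raised(self, small_cohort):
        m, man = small_cohort[0], small_cohort[1]
        out = pp.replace_zeros(m, man)
        assert ((out.data > 0).sum().sum()
                >= (m.data > 0).sum().sum())
        assert (m.data > 0).to_numpy().sum() == (
            (out.data.to_numpy() == m.data.to_numpy()) & (m.data > 0).to_numpy()
        ).sum()
        assert not (out.data == 0).any().any()


class TestHarmonizeBatches:
    def _two_batch(self, c=3.0, seed=5):
        rng = np.random.default_rng(seed)
        base = 10 ** rng.normal(1.0, 0.4, size=(12, 4))
        ids_a = [f"a{i}" for i in range(12)]
        ids_b = [f"b{i}" for i in range(12)]
        vals = np.vstack([base, base * c])
        roles = (["biological"] * 9 + ["PQC"] * 3) * 2
        man = make_manifest(ids_a + ids_b, role=roles,
                            batch=["B00"] * 12 + ["B01"] * 12)
        return _matrix(vals, ids=ids_a + ids_b), man

    def test_constant_batch_offset_removed(self):
        m, man = self._two_batch(c=3.0)
        out = pp.harmonize_batches(m, man)
        L = out.log10()
        man_i = man.set_index("sample_id")
        pqc = man_i.index[man_i["role"] == "PQC"]
        med = L.loc[pqc].groupby(man_i.loc[pqc, "batch"]).median()
        assert np.max(np.abs(med.loc["B00"] - med.loc["B01"])) < 1e-9

    def test_single_batch_is_noop(self):
        rng = np.random.default_rng(0)
        m = _matrix(10 ** rng.normal(0, 0.5, size=(10, 3)))
        man = make_manifest(m.sample_ids,
                            role=["biological"] * 7 + ["PQC"] * 3)
        out = pp.harmonize_batches(m, man)
        assert np.allclose(out.data, m.data, rtol=1e-10)

    def test_matches_stepwise_formula_oracle(self):
        m, man = self._two_batch(c=2.0, seed=17)
        # break the exact proportionality so scaling has work to do
        m.data.iloc[3, 1] *= 1.7
        m.data.iloc[15, 2] *= 0.6
        out = pp.harmonize_batches(m, man)
        expected = harmonize_oracle(m, man)
        assert np.allclose(out.data, expected, rtol=1e-10)

    def test_recovers_known_shifts_and_scales_exactly(self):
        pert, man, clean = make_harmonization_fixture(
            n_bio_per_batch=30, n_features=12,
            shifts=[0.4, -0.3, 0.0], scales=[1.4, 0.8, 0.9], seed=21)
        out = pp.harmonize_batches(pert, man)
        rel = np.abs(out.data - clean.data) / clean.data
        assert rel.to_numpy().max() < 1e-6

    def test_idempotent(self):
        m, man = self._two_batch(seed=9)
        once = pp.harmonize_batches(m, man)
        twice = pp.harmonize_batches(once, man)
        assert np.max(np.abs(twice.log10() - once.log10()).to_numpy()) < 1e-9

    def test_within_batch_rank_order_preserved(self):
        m, man = self._two_batch(seed=31)
        out = pp.harmonize_batches(m, man)
        man_i = man.set_index("sample_id")
        for b in ("B00", "B01"):
            ids = man_i.index[man_i["batch"] == b]
            before = m.data.loc[ids].rank()
            after = out.data.loc[ids].rank()
            pd.testing.assert_frame_equal(before, after)

    def test_missing_pqc_batch_is_named(self):
        m = _matrix(np.full((6, 2), 5.0))
        man = make_manifest(m.sample_ids, batch=["B00"] * 3 + ["B01"] * 3,
                            role=["biological", "biological", "PQC"] + ["biological"] * 3)
        with pytest.raises(lp.ValidationError, match="B01"):
            pp.harmonize_batches(m, man)


class TestImputeKnn:
    def test_nearest_duplicate_donates_its_value(self):
        m = _matrix([[1.0, 2.0, np.nan],
                     [1.0, 2.0, 7.0],
                     [100.0, 200.0, 9.0],
                     [110.0, 220.0, 9.5]])
        out = pp.impute_knn(m, make_manifest(m.sample_ids), k=1)
        assert out.data.iloc[0, 2] == pytest.approx(7.0)

    def test_no_missing_is_identity(self):
        m = _matrix([[1.0, 2.0], [3.0, 4.0]])
        out = pp.impute_knn(m, make_manifest(m.sample_ids), k=1)
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_hand_computed_two_neighbour_mean(self):
        # log10 values: A=(0,0,NaN), B=(0,1,1), C=(0,0.5,2), D=(3,3,3)
        # d(A,C)=0.5 < d(A,B)=1 < d(A,D); k=2 donors = {C,B}, mean log10 = 1.5
        m = _matrix(10.0 ** np.array([[0, 0, np.nan],
                                      [0, 1, 1],
                                      [0, 0.5, 2],
                                      [3, 3, 3]]), ids=list("abcd"))
        out = pp.impute_knn(m, make_manifest(m.sample_ids), k=2)
        assert out.data.loc["a", "f2"] == pytest.approx(10 ** 1.5, rel=1e-12)

    def test_observed_entries_never_change(self, small_cohort):
        m, man = small_cohort[0], small_cohort[1]
        m = pp.replace_zeros(m, man)
        out = pp.impute_knn(m, man, k=3)
        obs = ~m.missing_mask
        assert np.array_equal(out.data.to_numpy()[obs], m.data.to_numpy()[obs])
        assert not out.missing_mask.to_numpy().any()

    def test_feature_missing_everywhere_is_an_error(self):
        m = _matrix([[1.0, np.nan], [2.0, np.nan], [3.0, np.nan]])
        with pytest.raises(lp.ValidationError, match="f1"):
            pp.impute_knn(m, make_manifest(m.sample_ids), k=1)


class TestDetectOutliers:
    def _homogeneous(self, n=60, p=10, seed=2):
        rng = np.random.default_rng(seed)
        vals = 10 ** rng.normal(1.0, 0.15, size=(n, p))
        m = _matrix(vals)
        return m, make_manifest(m.sample_ids)

    def test_identical_samples_declare_nothing(self):
        m = _matrix(np.full((12, 4), 3.0))
        rep = pp.detect_outliers(m, make_manifest(m.sample_ids), n_components=2)
        assert rep.outliers == []
        assert (rep.pc_distance < 1e-9).all()

    def test_injected_extreme_sample_is_the_only_outlier(self):
        # homogeneous background: identical samples tie at the percentile, so
        # strict ">" declares only the planted extreme sample
        rng = np.random.default_rng(2)
        m = _matrix(np.tile(10 ** rng.normal(1.0, 0.5, size=10), (60, 1)))
        man = make_manifest(m.sample_ids)
        m2, ids = lp.inject_outliers(m, man, 1, 100.0, seed=4)
        rep = pp.detect_outliers(m2, man)
        assert rep.outliers == ids

    def test_intermediates_match_bruteforce_oracle(self):
        m, man = self._homogeneous(seed=8)
        m2, _ = lp.inject_outliers(m, man, 2, 50.0, seed=1)
        rep = pp.detect_outliers(m2, man)
        zsum, dist, ta, tb, A, B, declared = outlier_oracle(m2.log10())
        assert np.allclose(rep.zscore_sum.to_numpy(), zsum)
        assert np.allclose(rep.pc_distance.to_numpy(), dist, rtol=1e-8)
        assert rep.zsum_threshold == pytest.approx(ta)
        assert rep.distance_threshold == pytest.approx(tb, rel=1e-8)
        assert set(rep.flagged_zsum) == A
        assert set(rep.flagged_pca) == B
        assert set(rep.outliers) == declared

    def test_flagged_by_one_criterion_only_is_not_declared(self):
        # random data: the two 5% flag sets rarely coincide entirely
        rng = np.random.default_rng(15)
        m = _matrix(10 ** rng.normal(0, 0.3, size=(100, 20)))
        rep = pp.detect_outliers(m, make_manifest(m.sample_ids))
        only_a = set(rep.flagged_zsum) - set(rep.flagged_pca)
        assert only_a, "fixture should produce singly-flagged samples"
        assert only_a.isdisjoint(rep.outliers)
        assert set(rep.outliers) <= set(rep.flagged_zsum)
        assert set(rep.outliers) <= set(rep.flagged_pca)

    def test_report_is_bit_reproducible(self):
        m, man = self._homogeneous(seed=5)
        r1 = pp.detect_outliers(m, man)
        r2 = pp.detect_outliers(m, man)
        assert r1.zscore_sum.equals(r2.zscore_sum)
        assert r1.pc_distance.equals(r2.pc_distance)
        assert r1.outliers == r2.outliers

    def test_too_few_samples_rejected(self):
        m = _matrix(np.ones((5, 3)))
        with pytest.raises(lp.ValidationError):
            pp.detect_outliers(m, make_manifest(m.sample_ids), n_components=7)


class TestRetentionBookkeeping:
    def test_no_flags_retains_everything(self):
        man = make_manifest([f"s{i}" for i in range(10)])
        man2, summary = pp.apply_exclusions(man, None)
        assert summary.set_index("reason").loc["retained", "n"] == 10

    def test_overlapping_reasons_count_once(self):
        man = make_manifest(["a", "b", "c"],
                            exclusion=["maternal_contamination", "none", "none"])
        rep = pp.detect_outliers(
            _matrix(np.vstack([np.full((2, 3), 1.0),
                               np.full((1, 3), 1.0)]), ids=["a", "b", "c"]),
            make_manifest(["a", "b", "c"]), n_components=1)
        rep.outliers = ["a"]  # sample already contaminated
        man2, summary = pp.apply_exclusions(man, rep)
        s = summary.set_index("reason")["n"]
        assert s["excluded"] == 1 and s["retained"] == 2
        # original flag wins; the sample is not double-flagged
        assert (man2.set_index("sample_id").loc["a", "exclusion"]
                == "maternal_contamination")

    def test_unknown_outlier_id_rejected(self):
        man = make_manifest(["a", "b"])
        rep = pp.detect_outliers(_matrix(np.ones((2, 2)), ids=["a", "b"]),
                                 man, n_components=1)
        rep.outliers = ["zz"]
        with pytest.raises(lp.ValidationError, match="zz"):
            pp.apply_exclusions(man, rep)


class TestRetainFeatures:
    def _annotation(self, n=10, n_sim=3):
        rows = []
        for i in range(n):
            rows.append({
                "feature_id": f"f{i}", "lipid_class": "PC",
                "species": f"PC({i})", "mode": "SIM" if i < n_sim else "standard",
                "retained": True,
            })
        return validate_annotation(pd.DataFrame(rows))

    def test_single_drop(self):
        ann, counts = pp.retain_features(self._annotation(), ["f5"])
        assert counts["retained_measures"] == 9
        assert not ann.set_index("feature_id").loc["f5", "retained"]

    def test_empty_drop_list(self):
        _, counts = pp.retain_features(self._annotation(), [])
        assert counts["retained_measures"] == 10

    def test_species_view_excludes_sim(self):
        ann, counts = pp.retain_features(self._annotation(10, 3), [])
        assert counts["species_level_measures"] == 7
        assert len(pp.species_view(ann)) == 7

    def test_unknown_id_rejected(self):
        with pytest.raises(lp.ValidationError, match="nope"):
            pp.retain_features(self._annotation(), ["nope"])


class TestClassTotals:
    def _ann(self, rows):
        return validate_annotation(pd.DataFrame(
            rows, columns=["feature_id", "lipid_class", "species", "mode", "retained"]))

    def test_simple_sum(self):
        m = _matrix([[1.0, 2.0, 3.0]], cols=["x", "y", "z"])
        ann = self._ann([("x", "PC", "PC(1)", "standard", True),
                         ("y", "PC", "PC(2)", "standard", True),
                         ("z", "PC", "PC(3)", "standard", True)])
        out = pp.compute_class_totals(m, ann)
        assert out.data.iloc[0, 0] == pytest.approx(6.0)

    def test_tg_totals_use_sim_only(self):
        m = _matrix([[5.0, 5.0, 4.0, 6.0]], cols=["n1", "n2", "s1", "s2"])
        ann = self._ann([("n1", "TG", "TG(50:1)", "NL", True),
                         ("n2", "TG", "TG(52:2)", "NL", True),
                         ("s1", "TG", "TG(50:1) [SIM]", "SIM", True),
                         ("s2", "TG", "TG(52:2) [SIM]", "SIM", True)])
        out = pp.compute_class_totals(m, ann)
        assert out.data.loc[:, "TG"].iloc[0] == pytest.approx(10.0)

    def test_matches_groupby_oracle(self, small_cohort):
        m, man, ann, _ = small_cohort
        m = pp.replace_zeros(m, man)
        m = pp.impute_knn(m, man, k=3)
        out = pp.compute_class_totals(m, ann)
        for cls, grp in ann.groupby("lipid_class"):
            if cls in ("TG", "TG(O)"):
                feats = grp.loc[grp["mode"] == "SIM", "feature_id"]
            else:
                feats = grp.loc[grp["mode"] != "SIM", "feature_id"]
            expected = sum(m.data[f] for f in feats)
            assert np.allclose(out.data[cls], expected)

    def test_empty_class_is_an_error(self):
        m = _matrix([[1.0]], cols=["x"])
        ann = self._ann([("x", "TG", "TG(50:1)", "NL", True)])  # no SIM measure
        with pytest.raises(lp.ValidationError, match="TG"):
            pp.compute_class_totals(m, ann)
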