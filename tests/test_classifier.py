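import numpy as np
import pandas as pd
import pytest
from scipy import stats

from connectokin import classifier as clf
from connectokin import pairs as prs
from connectokin import synthetic as syn


@pytest.fixture(scope="module")
def planted_features(small_sim_module):
    sim, results = small_sim_module
    return clf.build_features(results, sim.cohort), sim.cohort


@pytest.fixture(scope="module")
def small_sim_module():
    """Module-level planted cohort with computed comparisons (cheap scale)."""
    from connectokin.preprocess import preprocess_scan, PreprocessConfig
    spec = syn.SyntheticSpec(
        family_templates=(("MZ", 2), ("DZ", 2), ("sib", 8), ("singleton", 4)),
        M=15, frames=240, g2=0.6, c2=0.2, e2=0.2, seed=21)
    sim = syn.simulate_cohort(spec)
    cfg = PreprocessConfig(profile="custom", do_censor=False, do_filter=False,
                           ar_order=1)
    residuals = {sid: preprocess_scan(ts, cfg=cfg)[0]
                 for sid, ts in sim.timeseries.items()}
    pairs = prs.enumerate_comparisons(sim.cohort)
    rng = np.random.default_rng(4)
    unrel = pairs[pairs["relationship"] == "unrelated"]
    keep = pairs[pairs["relationship"].isin(prs.SIBLING_CLASSES)]
    take = unrel.iloc[rng.choice(len(unrel), size=160, replace=False)]
    subset = pd.concat([keep, take], ignore_index=True)
    results = prs.run_all_comparisons(sim.cohort, residuals, pairs=subset)
    return sim, results


class TestBuildFeatures:
    def test_row_per_comparison_with_label(self, planted_features):
        fs, cohort = planted_features
        assert fs.X.shape[0] == len(fs.y) == len(fs.meta)
        assert fs.X.shape[1] == 15
        assert fs.y.sum() == 24  # (2+2+8) pairs x 2 directions

    def test_self_comparisons_excluded(self, planted_features):
        fs, _ = planted_features
        assert not fs.meta["relationship"].str.startswith("self").any()

    def test_no_positive_class_rejected(self, small_sim_module):
        sim, results = small_sim_module
        tab = results.table
        unrel_only = tab["relationship"] == "unrelated"
        sub = prs.ComparisonResults(table=tab[unrel_only].reset_index(drop=True),
                                    per_roi=results.per_roi[unrel_only.to_numpy()])
        with pytest.raises(ValueError, match="no positive class"):
            clf.build_features(sub, sim.cohort)


class TestKSRanking:
    def test_matches_scipy_oracle(self, rng):
        for _ in range(20):
            a = rng.standard_normal(rng.integers(5, 30))
            b = rng.standard_normal(rng.integers(5, 30)) + rng.normal(0, 1)
            expected = stats.ks_2samp(a, b).statistic
            assert clf.ks_statistic(a, b) == pytest.approx(expected, abs=1e-12)

    def test_known_value(self):
        # {1,2,3} vs {2,3,4}: D = 1/3 by direct ECDF comparison
        assert clf.ks_statistic([1, 2, 3], [2, 3, 4]) == pytest.approx(1 / 3)

    def test_identical_distributions_zero(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert clf.ks_statistic(x, x) == 0.0

    def test_separated_classes_rank_first(self, rng):
        X = rng.standard_normal((40, 5))
        y = np.r_[np.ones(20), np.zeros(20)].astype(int)
        X[y == 1, 2] += 10.0  # fully separated feature
        X[:, 4] = 1.0  # constant feature
        order, D = clf.rank_features_ks(X, y)
        assert order[0] == 2 and D[2] == 1.0
        assert D[4] == 0.0 and order[-1] == 4


class TestTunedSVM:
    def test_separable_loocv_perfect(self, rng):
        X = np.vstack([rng.normal(0, 0.2, (15, 2)), rng.normal(3, 0.2, (15, 2))])
        y = np.r_[np.zeros(15), np.ones(15)].astype(int)
        model = clf.train_tuned_svm(X, y)
        assert model.loocv_accuracy == 1.0
        assert (model.predict(X) == y).all()

    def test_random_labels_chance_level(self, rng):
        X = rng.standard_normal((60, 10))
        y = rng.permutation(np.r_[np.zeros(30), np.ones(30)]).astype(int)
        model = clf.train_tuned_svm(X, y)
        assert 0.2 <= model.loocv_accuracy <= 0.75

    def test_top_p_clipped(self, rng):
        X = rng.standard_normal((30, 5))
        y = np.r_[np.zeros(15), np.ones(15)].astype(int)
        X[y == 1] += 1.0
        model = clf.train_tuned_svm(X, y, top_p=50)
        assert len(model.feature_idx) == 5

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="single-class"):
            clf.train_tuned_svm(rng.standard_normal((10, 3)),
                                np.ones(10, dtype=int))

    def test_loocv_shortcut_matches_naive(self, rng):
        """The non-support-vector LOO shortcut equals brute-force LOOCV."""
        from sklearn.svm import SVC
        X = rng.standard_normal((24, 4))
        y = np.r_[np.zeros(12), np.ones(12)].astype(int)
        X[y == 1] += 0.8
        for C in (0.01, 1.0, 100.0):
            naive = 0
            idx = np.arange(24)
            for i in range(24):
                m = SVC(kernel="linear", C=C, max_iter=clf.SVC_MAX_ITER)
                m.fit(X[idx != i], y[idx != i])
                naive += int(m.predict(X[i:i + 1])[0] == y[i])
            assert clf._loocv_accuracy(X, y, C) == pytest.approx(naive / 24)


class TestExperiments:
    def test_planted_signal_beats_null(self, planted_features):
        fs, cohort = planted_features
        res = clf.run_experiment(fs, cohort, scheme="family_holdout", runs=15,
                                 null_runs=15, holdout_families=2, top_p=15,
                                 seed=3)
        assert res.accuracy.mean() > res.null_accuracy.mean() + 0.2

    def test_scanpair_scheme_runs(self, planted_features):
        fs, cohort = planted_features
        res = clf.run_experiment(fs, cohort, scheme="scanpair_holdout", runs=8,
                                 null_runs=4, holdout_families=2, top_p=15,
                                 seed=3)
        assert res.accuracy.shape == (8,)
        assert np.isfinite(res.accuracy).all()

    def test_summary_bands_ordered(self, planted_features):
        fs, cohort = planted_features
        res = clf.run_experiment(fs, cohort, runs=10, null_runs=5,
                                 holdout_families=2, top_p=15, seed=9)
        s = res.summary()["accuracy"]
        assert s["p2.5"] <= s["p25"] <= s["p75"] <= s["p97.5"]

    def test_stratified_accuracies_reported(self, planted_features):
        fs, cohort = planted_features
        res = clf.run_experiment(fs, cohort, runs=20, null_runs=2,
                                 holdout_families=2, top_p=15, seed=5)
        strata = clf.stratify_by_zygosity(res)
        assert strata["sibling"] is not None

    def test_too_few_families_rejected(self, planted_features):
        fs, cohort = planted_features
        with pytest.raises(ValueError):
            clf.run_experiment(fs, cohort, runs=2, holdout_families=50, seed=0)

    def test_cross_dataset_same_generator_generalizes(self, planted_features,
                                                      small_sim_module):
        fs, cohort = planted_features
        # second cohort drawn with the same generative parameters, new seed
        from connectokin.preprocess import preprocess_scan, PreprocessConfig
        # same generative parameters and shared structural "brain"
        # (structure_seed), fresh subjects and a different scan length
        spec2 = syn.SyntheticSpec(
            family_templates=(("sib", 8), ("singleton", 2)),
            M=15, frames=150, g2=0.6, c2=0.2, e2=0.2, seed=77,
            structure_seed=21)
        sim2 = syn.simulate_cohort(spec2)
        cfg = PreprocessConfig(profile="custom", do_censor=False,
                               do_filter=False, ar_order=1)
        residuals = {sid: preprocess_scan(ts, cfg=cfg)[0]
                     for sid, ts in sim2.timeseries.items()}
        pairs = prs.enumerate_comparisons(sim2.cohort)
        rng = np.random.default_rng(8)
        unrel = pairs[pairs["relationship"] == "unrelated"]
        keep = pairs[pairs["relationship"].isin(prs.SIBLING_CLASSES)]
        take = unrel.iloc[rng.choice(len(unrel), size=80, replace=False)]
        results2 = prs.run_all_comparisons(
            sim2.cohort, residuals,
            pairs=pd.concat([keep, take], ignore_index=True))
        fs2 = clf.build_features(results2, sim2.cohort)
        res = clf.cross_dataset_experiment(fs, fs2, runs=10, null_runs=10,
                                           top_p=15, seed=2)
        assert res.accuracy.mean() > res.null_accuracy.mean() + 0.15

    def test_per_network_experiments_run(self, planted_features,
                                         small_sim_module):
        sim, _ = small_sim_module
        fs, cohort = planted_features
        out = clf.per_network_experiment(fs, cohort, sim.parcellation, runs=3,
                                         holdout_families=2, seed=1)
        assert len(out) >= 2
        for net, res in out.items():
            cols = sim.parcellation.network_members(net)
            assert len(cols) >= 2
            assert np.isfinite(res.accuracy).all()

    def test_cross_dataset_parcellation_mismatch_rejected(self, planted_features):
        fs, _ = planted_features
        fs2 = clf.FeatureSet(fs.X[:, :10], fs.y, fs.meta)
        with pytest.raises(ValueError, match="parcellation"):
            clf.cross_dataset_experiment(fs, fs2, runs=1, seed=0)


@pytest.fixture(scope="module")
def anat_cohort():
    spec = syn.SyntheticSpec(
        family_templates=(("MZ", 2), ("sib", 4), ("singleton", 4)),
        M=10, frames=100, seed=13)
    sim = syn.simulate_cohort(spec, with_anatomy=True)
    return sim.cohort


class TestAnatomicalFeatures:

    def test_identical_anatomy_gives_zero_features(self, anat_cohort):
        cohort = anat_cohort
        a = cohort.anatomy
        mz = cohort.zygosity_pairs[cohort.zygosity_pairs["zygosity"] == "MZ"].iloc[0]
        # force identical anatomy for one MZ pair
        cohort.anatomy = a.copy()
        rows_b = cohort.anatomy["subject_id"] == mz["subject_b"]
        donor = a[a["subject_id"] == mz["subject_a"]].set_index("roi_id")
        for col in ("thickness", "sulcal_depth", "head_size"):
            cohort.anatomy.loc[rows_b, col] = donor.loc[
                cohort.anatomy.loc[rows_b, "roi_id"], col].to_numpy()
        pairs = pd.DataFrame([{"subject_a": mz["subject_a"],
                               "subject_b": mz["subject_b"],
                               "relationship": "MZ"}])
        fs = clf.anatomical_features(cohort, pairs, measure="thickness")
        assert np.abs(fs.X).max() < 1e-12
        cohort.anatomy = a

    def test_normalize_divides_by_head_size(self, anat_cohort):
        pairs = clf.enumerate_subject_pairs(anat_cohort, n_unrelated=5, seed=0)
        raw = clf.anatomical_features(anat_cohort, pairs, adjust="none")
        norm = clf.anatomical_features(anat_cohort, pairs, adjust="normalize")
        head = anat_cohort.anatomy.groupby("subject_id")["head_size"].first()
        a = pairs.iloc[0]["subject_a"]
        b = pairs.iloc[0]["subject_b"]
        wide = anat_cohort.anatomy.pivot(index="subject_id", columns="roi_id",
                                         values="thickness")
        expected = wide.loc[a].to_numpy() / head[a] - wide.loc[b].to_numpy() / head[b]
        np.testing.assert_allclose(norm.X[0], expected)
        assert not np.allclose(raw.X[0], norm.X[0])

    def test_regress_removes_head_size_correlation(self, anat_cohort):
        wide = anat_cohort.anatomy.pivot(index="subject_id", columns="roi_id",
                                         values="thickness")
        head = anat_cohort.anatomy.groupby("subject_id")["head_size"].first() \
            .reindex(wide.index).to_numpy()
        Xh = np.column_stack([np.ones_like(head), head])
        beta, *_ = np.linalg.lstsq(Xh, wide.to_numpy(), rcond=None)
        resid = wide.to_numpy() - Xh @ beta
        hc = head - head.mean()
        for j in range(resid.shape[1]):
            rc = resid[:, j] - resid[:, j].mean()
            assert abs(hc @ rc) / (np.linalg.norm(hc) * np.linalg.norm(rc) + 1e-30) < 1e-8


class TestRoiSizeConfound:
    def test_ks_machinery_on_constructed_tables(self, rng):
        parc = syn.make_parcellation(n_cortical=50, n_unassigned=5,
                                     n_subcortical=0, seed=1)
        # selection independent of size -> large p
        counts = rng.random(50)
        k, p = clf.roi_size_confound(counts, parc, top_n=20)
        assert 0 <= k <= 1
        # selection aligned with size -> small p, large k
        sizes = parc.table["n_vertices"].to_numpy().astype(float)
        k2, p2 = clf.roi_size_confound(sizes, parc, top_n=20)
        assert k2 > k and p2 < 0.05
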