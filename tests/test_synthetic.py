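import numpy as np
import pytest

from connectokin import synthetic as syn


class TestPedigree:
    def test_hcp_shaped_cohort(self):
        """70 one- + 49 two- + 10 three-descendant families -> 198 subjects
        carrying 10 MZ + 11 DZ + 58 nontwin sibling pairs."""
        spec = syn.SyntheticSpec(M=6, frames=40, seed=0)
        cohort = syn.make_pedigree(spec)
        assert cohort.n_subjects == 198
        assert len(cohort.zygosity_pairs) == 79
        zc = cohort.zygosity_pairs["zygosity"].value_counts()
        assert zc["MZ"] == 10 and zc["DZ"] == 11 and zc["sibling"] == 58

    def test_single_singleton(self):
        spec = syn.SyntheticSpec(family_templates=(("singleton", 1),),
                                 M=6, frames=40, seed=0)
        cohort = syn.make_pedigree(spec)
        assert cohort.n_subjects == 1
        assert len(cohort.zygosity_pairs) == 0

    def test_pairs_share_family(self, small_sim):
        cohort = small_sim.cohort
        fam = dict(zip(cohort.subjects["subject_id"],
                       cohort.subjects["family_id"]))
        for _, row in cohort.zygosity_pairs.iterrows():
            assert fam[row["subject_a"]] == fam[row["subject_b"]]

    def test_zero_families_rejected(self):
        spec = syn.SyntheticSpec(family_templates=(), M=6, frames=40, seed=0)
        with pytest.raises(ValueError, match="zero families"):
            syn.make_pedigree(spec)


class TestPrecisions:
    def test_pure_genetic_mz_identical(self):
        spec = syn.SyntheticSpec(
            family_templates=(("MZ", 3), ("singleton", 2)),
            M=10, frames=40, g2=1.0, c2=0.0, e2=0.0, seed=1)
        cohort = syn.make_pedigree(spec)
        truth = syn.make_precisions(spec, cohort)
        for _, row in cohort.zygosity_pairs.iterrows():
            np.testing.assert_allclose(truth.precisions[row["subject_a"]],
                                       truth.precisions[row["subject_b"]])

    def test_pure_unique_no_cross_subject_correlation(self):
        spec = syn.SyntheticSpec(
            family_templates=(("sib", 25),), M=25, frames=40,
            g2=0.0, c2=0.0, e2=1.0, seed=2)
        cohort = syn.make_pedigree(spec)
        truth = syn.make_precisions(spec, cohort)
        e = truth.edge_index
        corrs = []
        for _, row in cohort.zygosity_pairs.iterrows():
            wa = truth.precisions[row["subject_a"]][e[:, 0], e[:, 1]]
            wb = truth.precisions[row["subject_b"]][e[:, 0], e[:, 1]]
            corrs.append(np.corrcoef(wa, wb)[0, 1])
        assert abs(np.mean(corrs)) < 0.15

    def test_dz_edge_correlation_half_under_pure_genetics(self):
        corrs = []
        for seed in range(4):
            spec = syn.SyntheticSpec(
                family_templates=(("DZ", 12),), M=30, frames=40,
                g2=1.0, c2=0.0, e2=0.0, base_weight_sd=0.0, seed=seed)
            cohort = syn.make_pedigree(spec)
            truth = syn.make_precisions(spec, cohort)
            e = truth.edge_index
            for _, row in cohort.zygosity_pairs.iterrows():
                wa = truth.precisions[row["subject_a"]][e[:, 0], e[:, 1]]
                wb = truth.precisions[row["subject_b"]][e[:, 0], e[:, 1]]
                corrs.append(np.corrcoef(wa, wb)[0, 1])
        assert np.mean(corrs) == pytest.approx(0.5, abs=0.05)

    def test_localized_familial_signal(self):
        """familial_rois restricts kinship-correlated edges to the incident
        set; other edges stay subject-unique."""
        spec = syn.SyntheticSpec(
            family_templates=(("MZ", 10),), M=20, frames=40,
            g2=1.0, c2=0.0, e2=0.0, base_weight_sd=0.0,
            familial_rois=tuple(range(5)), seed=3)
        cohort = syn.make_pedigree(spec)
        truth = syn.make_precisions(spec, cohort)
        e, fam_mask = truth.edge_index, truth.familial_edges
        assert fam_mask.any() and not fam_mask.all()
        for _, row in cohort.zygosity_pairs.iterrows():
            Ta = truth.precisions[row["subject_a"]]
            Tb = truth.precisions[row["subject_b"]]
            wa, wb = Ta[e[:, 0], e[:, 1]], Tb[e[:, 0], e[:, 1]]
            # MZ twins identical on familial edges, independent elsewhere
            np.testing.assert_allclose(wa[fam_mask], wb[fam_mask])
            assert not np.allclose(wa[~fam_mask], wb[~fam_mask])

    def test_shared_structure_seed_same_support(self):
        a = syn.SyntheticSpec(family_templates=(("sib", 3),), M=15, frames=40,
                              seed=1, structure_seed=99)
        b = syn.SyntheticSpec(family_templates=(("sib", 5),), M=15, frames=40,
                              seed=2, structure_seed=99)
        ta = syn.make_precisions(a, syn.make_pedigree(a))
        tb = syn.make_precisions(b, syn.make_pedigree(b))
        np.testing.assert_array_equal(ta.edge_index, tb.edge_index)

    def test_spd_and_b_definition(self, small_sim):
        truth = small_sim.truth
        for s, Theta in truth.precisions.items():
            assert np.linalg.eigvalsh(Theta)[0] >= 0.1 - 1e-9
            B = truth.B_true[s]
            assert np.allclose(np.diag(B), 0.0)
            i, j = 0, 1
            assert B[i, j] == pytest.approx(-Theta[i, j] / Theta[i, i])

    def test_planted_similarity_ordering(self):
        spec = syn.SyntheticSpec(
            family_templates=(("MZ", 6), ("DZ", 6), ("sib", 6), ("singleton", 6)),
            M=20, frames=40, g2=0.6, c2=0.1, e2=0.3, seed=5)
        cohort = syn.make_pedigree(spec)
        truth = syn.make_precisions(spec, cohort)
        sims = syn.expected_pair_similarity_ordering(truth)
        assert sims["MZ"] > sims["DZ_or_sib"] > sims["unrelated"]


class TestSampleTimeseries:
    def test_sample_covariance_matches_inverse_precision(self):
        spec = syn.SyntheticSpec(family_templates=(("singleton", 1),),
                                 M=10, frames=5000, ar_phi=0.0, seed=4)
        cohort = syn.make_pedigree(spec)
        truth = syn.make_precisions(spec, cohort)
        s = cohort.subjects["subject_id"].iloc[0]
        rng = np.random.default_rng(9)
        ts = syn.sample_timeseries(truth, s, "x", rng)
        emp = np.cov(ts.data, rowvar=False)
        cov = np.linalg.inv(truth.precisions[s])
        rel = np.linalg.norm(emp - cov) / np.linalg.norm(cov)
        assert rel < 0.1

    def test_ar_phi_zero_gives_white_series(self):
        spec = syn.SyntheticSpec(family_templates=(("singleton", 1),),
                                 M=8, frames=2000, ar_phi=0.0, seed=6)
        cohort = syn.make_pedigree(spec)
        truth = syn.make_precisions(spec, cohort)
        rng = np.random.default_rng(2)
        ts = syn.sample_timeseries(truth, cohort.subjects["subject_id"].iloc[0],
                                   "x", rng)
        x = ts.data[:, 0] - ts.data[:, 0].mean()
        rho1 = (x[:-1] @ x[1:]) / (x @ x)
        assert abs(rho1) < 0.05

    def test_ar_phi_positive_induces_autocorrelation(self):
        spec = syn.SyntheticSpec(family_templates=(("singleton", 1),),
                                 M=8, frames=2000, ar_phi=0.5, seed=6)
        cohort = syn.make_pedigree(spec)
        truth = syn.make_precisions(spec, cohort)
        rng = np.random.default_rng(2)
        ts = syn.sample_timeseries(truth, cohort.subjects["subject_id"].iloc[0],
                                   "x", rng)
        x = ts.data[:, 0] - ts.data[:, 0].mean()
        rho1 = (x[:-1] @ x[1:]) / (x @ x)
        assert rho1 == pytest.approx(0.5, abs=0.1)

    def test_end_to_end_connectotype_recovery(self):
        """fit_connectotype on long scans recovers B_true within +-0.05."""
        from connectokin.connectotype import fit_connectotype
        spec = syn.SyntheticSpec(family_templates=(("singleton", 1),),
                                 M=12, frames=5000, ar_phi=0.0, seed=8)
        cohort = syn.make_pedigree(spec)
        truth = syn.make_precisions(spec, cohort)
        s = cohort.subjects["subject_id"].iloc[0]
        rng = np.random.default_rng(11)
        ts = syn.sample_timeseries(truth, s, "x", rng)
        model = fit_connectotype(ts, rank=11)
        assert np.abs(model.B - truth.B_true[s]).max() < 0.05


class TestFD:
    def test_no_shift_null_family_similarity(self, rng):
        a = syn.make_fd(500, rng)
        b = syn.make_fd(500, rng)
        assert abs(np.median(a) - np.median(b)) < 0.05

    def test_family_shift_separates_medians(self, rng):
        base = syn.make_fd(500, rng)
        shifted = syn.make_fd(500, rng, shift=0.3)
        assert np.median(shifted) - np.median(base) > 0.2

    def test_default_trace_mostly_retained_at_threshold(self, rng):
        from connectokin.preprocess import censor_frames
        fd = syn.make_fd(1000, rng, median=0.1)
        res = censor_frames(fd, tr=2.5)
        assert res.mask.mean() > 0.5


class TestDeterminism:
    def test_identical_spec_reproduces_bit_identical_data(self):
        spec = syn.SyntheticSpec(family_templates=(("sib", 2), ("singleton", 1)),
                                 M=8, frames=60, seed=42)
        a = syn.simulate_cohort(spec)
        b = syn.simulate_cohort(spec)
        assert list(a.timeseries) == list(b.timeseries)
        for sid in a.timeseries:
            np.testing.assert_array_equal(a.timeseries[sid].data,
                                          b.timeseries[sid].data)
            np.testing.assert_array_equal(a.fd[sid], b.fd[sid])


class TestPairOutcomeGenerator:
    def test_group_mean_ordering(self):
        po = syn.make_pair_outcomes(h2=0.2, c2=0.2, n_per_group=40, seed=0)
        mz = po.Y[po.genetics == "MZ"].mean()
        dz = po.Y[po.genetics == "DZ_or_sib"].mean()
        un = po.Y[po.genetics == "unrelated"].mean()
        assert mz > dz > un

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            syn.make_pair_outcomes(h2=0.7, c2=0.4)
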