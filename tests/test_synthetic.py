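"""Generators: structural invariants, statistical checks against closed
forms, and the recovery-report contract."""

import numpy as np
import pytest
from scipy import stats

from varmerge import SyntheticSpec, make_toy, simulate
from varmerge.reflection_io import (read_reflections, standardize_metadata,
                                    write_merged)
from varmerge.symmetry import annotate, group_harmonics, spacegroup_ops


class TestToy:
    def test_shape_and_composition(self):
        table, truth = make_toy(seed=0)
        assert len(table) == 30
        assert len(np.unique(table.miller(), axis=0)) == 3
        counts = np.unique(table.df["h"], return_counts=True)[1]
        assert counts.tolist() == [10, 10, 10]

    def test_true_intensity_is_scale_times_squared_amplitude(self):
        table, truth = make_toy(seed=0)
        F_rows = truth.F_true[table.df["h"].to_numpy() - 1]
        np.testing.assert_allclose(truth.I_true,
                                   truth.Sigma_true * F_rows ** 2, rtol=1e-12)

    def test_same_seed_identical(self):
        t1, _ = make_toy(seed=5)
        t2, _ = make_toy(seed=5)
        np.testing.assert_array_equal(t1.df.to_numpy(), t2.df.to_numpy())


class TestSimulate:
    def test_zero_noise_is_exact(self):
        spec = SyntheticSpec(n_unique=40, multiplicity=4.0,
                             noise_level=0.0, seed=0)
        table, truth = simulate(spec)
        np.testing.assert_allclose(table.df["intensity"].to_numpy(),
                                   truth["I_true"], rtol=1e-12)

    def test_wilson_second_moment_of_amplitudes(self):
        spec = SyntheticSpec(n_unique=5000, multiplicity=1.0, hmax=20, seed=1)
        table, truth = simulate(spec)
        tu = truth["unique"]
        acentric = ~tu["centric"].to_numpy(bool)
        ratio = tu["F"].to_numpy()[acentric] ** 2 / \
            tu["epsilon"].to_numpy()[acentric]
        se = ratio.std() / np.sqrt(acentric.sum())
        assert abs(ratio.mean() - 1.0) < 3 * se

    def test_outlier_count_is_binomial_consistent(self):
        spec = SyntheticSpec(n_unique=300, multiplicity=6.0,
                             outlier_fraction=0.1, seed=2)
        table, truth = simulate(spec)
        # outliers are drawn per ray observation
        n = len(truth["outlier"])
        k = truth["outlier"].sum()
        sd = np.sqrt(n * 0.1 * 0.9)
        assert abs(k - 0.1 * n) < 4 * sd

    def test_symmetry_correct_epsilon_in_p212121(self):
        spec = SyntheticSpec(n_unique=100, multiplicity=2.0,
                             space_group="P212121", seed=3)
        table, truth = simulate(spec)
        ops = spacegroup_ops("P212121")
        df = annotate(table, ops)
        tu = truth["unique"].set_index(["asu_h", "asu_k", "asu_l"])
        for (h, k, l), eps in df.groupby(["asu_h", "asu_k", "asu_l"])[
                "epsilon"].first().items():
            assert tu.loc[(h, k, l), "epsilon"] == eps

    def test_harmonic_rays_sum_member_contributions(self):
        spec = SyntheticSpec(n_unique=60, multiplicity=4.0,
                             harmonic_fraction=0.3, noise_level=0.0, seed=4)
        table, truth = simulate(spec)
        groups = group_harmonics(table)
        sizes = groups.sizes
        assert (sizes == 2).any()
        # grouped ray intensity equals the sum of member Sigma * F^2
        contrib = truth["I_true"]
        for r in np.flatnonzero(sizes == 2)[:10]:
            rows = np.flatnonzero(groups.ray_id == r)
            assert groups.ray_intensity[r] == pytest.approx(
                contrib[rows].sum(), rel=1e-9)

    def test_wavelength_metadata_only_in_laue_mode(self):
        mono = simulate(SyntheticSpec(n_unique=30, seed=5))[0]
        laue = simulate(SyntheticSpec(n_unique=30, harmonic_fraction=0.2,
                                      seed=5))[0]
        assert "wavelength" not in mono.metadata_columns
        assert "wavelength" in laue.metadata_columns

    def test_two_datasets_share_unchanged_amplitudes(self):
        spec = SyntheticSpec(n_unique=80, multiplicity=2.0, n_datasets=2,
                             changed_fraction=0.25, change_scale=0.02, seed=6)
        table, truth = simulate(spec)
        tu = truth["unique"]
        p = tu.pivot_table(index=["asu_h", "asu_k", "asu_l"],
                           columns="dataset_id", values=["F", "changed"])
        same = ~p[("changed", 0)].astype(bool)
        np.testing.assert_array_equal(p[("F", 0)][same], p[("F", 1)][same])
        changed = p[("changed", 0)].astype(bool)
        rel = (p[("F", 1)][changed] - p[("F", 0)][changed]).abs() \
            / p[("F", 0)][changed]
        np.testing.assert_allclose(rel, 0.02, rtol=1e-9)

    def test_anomalous_differences_only_on_acentrics(self):
        spec = SyntheticSpec(n_unique=100, multiplicity=2.0,
                             space_group="P212121", anomalous_signal=0.05,
                             seed=7)
        table, truth = simulate(spec)
        tu = truth["unique"]
        cen = tu["centric"].to_numpy(bool)
        d = (tu["F_plus"] - tu["F_minus"]).to_numpy()
        np.testing.assert_array_equal(d[cen], 0.0)
        assert np.any(d[~cen] != 0.0)

    def test_output_passes_io_validation_roundtrip(self, tmp_path):
        spec = SyntheticSpec(n_unique=40, multiplicity=3.0, seed=8)
        table, _ = simulate(spec)
        path = tmp_path / "sim.csv"
        table.df.rename(columns={"image_id": "image", "intensity": "I",
                                 "sigma_I": "SigI"}).to_csv(path, index=False)
        back = read_reflections(path)
        assert len(back) == len(table)
        assert set(back.metadata_columns) == {"phi", "dspacing"}
        X, _, _ = standardize_metadata(back)
        assert np.isfinite(X).all()

    def test_same_seed_identical(self):
        spec = SyntheticSpec(n_unique=30, seed=9)
        t1, _ = simulate(spec)
        t2, _ = simulate(spec)
        np.testing.assert_array_equal(t1.df.to_numpy(), t2.df.to_numpy())

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(outlier_fraction=0.7, seed=0)
        with pytest.raises(ValueError):
            SyntheticSpec(harmonic_fraction=1.2, seed=0)


class TestRecoveryReport:
    def test_collapsed_posterior_scores_perfectly(self):
        from varmerge import ScaleConfig, TrainingConfig, fit, recovery_report
        from varmerge.posteriors import constrain_inverse
        spec = SyntheticSpec(n_unique=30, multiplicity=3.0, seed=10)
        table, truth = simulate(spec)
        res = fit(table, "P1", training=TrainingConfig(iterations=0, seed=0))
        # collapse the posterior onto the truth
        tu = truth["unique"]
        j = res.unique_map.unique.merge(
            tu, on=["asu_h", "asu_k", "asu_l", "dataset_id"], how="left")
        res.posterior.raw_loc.data = constrain_inverse(j["F"].to_numpy())
        res.posterior.raw_scale.data = constrain_inverse(
            1e-6 * j["F"].to_numpy())
        rep = recovery_report(res, truth)
        assert rep["pearson_F"] == pytest.approx(1.0, abs=1e-9)
        assert rep["spearman_F"] == pytest.approx(1.0, abs=1e-9)
        assert rep["coverage_95"] == 1.0

    def test_prior_only_fit_report_is_well_formed(self):
        from varmerge import TrainingConfig, fit, recovery_report
        spec = SyntheticSpec(n_unique=30, multiplicity=3.0, seed=11)
        table, truth = simulate(spec)
        res = fit(table, "P1", training=TrainingConfig(iterations=0, seed=0))
        rep = recovery_report(res, truth)
        assert set(rep) >= {"pearson_F", "spearman_F", "coverage_95"}
        assert -1.0 <= rep["pearson_F"] <= 1.0
        assert 0.0 <= rep["coverage_95"] <= 1.0
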