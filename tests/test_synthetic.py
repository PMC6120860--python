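"""Ground-truth guarantees of the synthetic angiogram and cohort generator."""

import numpy as np
import pandas as pd
import pytest

from octara.metrics import change_over_time
from octara.synthetic import (
    CohortSpec,
    ImageSpec,
    degrade_angiogram,
    generate_angiogram,
    generate_choriocapillaris,
    generate_cohort,
    generate_ez_profile,
    sample_bivariate,
    _faz_ring,
)


class TestGenerateAngiogram:
    def test_truth_hits_targets(self, spec245):
        a, truth = generate_angiogram(spec245, 33.4, 0.345, seed=1)
        assert 32.9 <= truth.true_pd_pct <= 33.9
        px_area = spec245.scale_mm_per_px**2
        assert abs(truth.true_faz_mm2 - 0.345) <= px_area

    def test_truth_consistency_by_independent_recount(self, spec245):
        """Recomputing PD/FAZ from the emitted masks reproduces the truth."""
        _, truth = generate_angiogram(spec245, 24.5, 0.784, seed=4, slab="DCP")
        n_vessel = int(np.count_nonzero(truth.vessel_mask))
        n_faz = int(np.count_nonzero(truth.faz_mask))
        assert truth.true_pd_pct == 100.0 * n_vessel / (245 * 245 - n_faz)
        assert truth.true_faz_mm2 == n_faz * spec245.scale_mm_per_px**2
        assert not (truth.vessel_mask & truth.faz_mask).any()

    def test_zero_density_gives_background_image(self, spec245):
        a, truth = generate_angiogram(spec245, 0.0, 0.0, seed=2)
        assert truth.true_pd_pct == 0.0
        assert not truth.vessel_mask.any()

    def test_seed_determinism_bit_identical(self, spec245):
        a1, t1 = generate_angiogram(spec245, 30.0, 0.4, seed=11)
        a2, t2 = generate_angiogram(spec245, 30.0, 0.4, seed=11)
        assert np.array_equal(a1.pixels, a2.pixels)
        assert np.array_equal(t1.vessel_mask, t2.vessel_mask)

    def test_unreachable_targets_fail_loudly(self, spec245):
        with pytest.raises(ValueError, match="does not fit"):
            generate_angiogram(spec245, 30.0, 8.5, seed=0)
        with pytest.raises(ValueError, match="\\[0, 100\\)"):
            generate_angiogram(spec245, 100.0, 0.3, seed=0)


class TestDegradeAngiogram:
    def test_requested_deltas_achieved(self, spec245):
        _, t1 = generate_angiogram(spec245, 33.4, 0.345, seed=3)
        _, t2 = degrade_angiogram(t1, -3.0, 0.10, seed=5)
        px_area = spec245.scale_mm_per_px**2
        assert t2.true_pd_pct - t1.true_pd_pct == pytest.approx(-3.0, abs=0.5)
        assert t2.true_faz_mm2 - t1.true_faz_mm2 == pytest.approx(0.10, abs=px_area)

    def test_monotone_degradation(self, spec245):
        """Decline prunes the network; FAZ growth only accretes pixels."""
        _, t1 = generate_angiogram(spec245, 33.4, 0.345, seed=3)
        _, t2 = degrade_angiogram(t1, -3.0, 0.10, seed=5)
        assert (t1.faz_mask <= t2.faz_mask).all()
        # with an unchanged FAZ, a pure density decline never adds a vessel
        _, t3 = degrade_angiogram(t1, -3.0, 0.0, seed=5)
        assert (t3.vessel_mask <= t1.vessel_mask).all()

    def test_zero_deltas_keep_truth(self, spec245):
        _, t1 = generate_angiogram(spec245, 28.0, 0.5, seed=9)
        _, t2 = degrade_angiogram(t1, 0.0, 0.0, seed=10)
        assert t2.true_pd_pct == pytest.approx(t1.true_pd_pct, abs=1e-9)
        assert t2.true_faz_mm2 == t1.true_faz_mm2

    def test_implied_yearly_rate(self, spec245):
        _, t1 = generate_angiogram(spec245, 33.4, 0.345, seed=3)
        _, t2 = degrade_angiogram(t1, -3.14, 0.0, seed=6)
        rate = change_over_time(t1.true_pd_pct, t2.true_pd_pct, 1.3)
        assert rate == pytest.approx(-3.14 / 1.3, abs=0.01)

    def test_excessive_decline_fails(self, spec245):
        _, t1 = generate_angiogram(spec245, 10.0, 0.3, seed=3)
        with pytest.raises(ValueError, match="\\(0, 100\\)"):
            degrade_angiogram(t1, -15.0, 0.0, seed=4)


class TestChoriocapillaris:
    def test_noiseless_is_constant_at_nearest_level(self, spec245):
        cc = generate_choriocapillaris(spec245, 99.5, noise_sd=0.0, seed=0)
        assert np.ptp(cc.pixels) == 0
        assert cc.pixels[0, 0] == round(99.5)  # nearest representable level

    def test_zero_target_all_black(self, spec245):
        cc = generate_choriocapillaris(spec245, 0.0, noise_sd=0.0, seed=1)
        assert not cc.pixels.any()

    def test_sample_mean_within_standard_error(self, spec245):
        cc = generate_choriocapillaris(spec245, 128.0, noise_sd=10.0, seed=2)
        se = 10.0 / 245
        assert cc.pixels.mean() == pytest.approx(128.0, abs=3 * se + 0.05)

    def test_out_of_range_target_rejected(self, spec245):
        with pytest.raises(ValueError, match="\\[0, 255\\]"):
            generate_choriocapillaris(spec245, 300.0)


class TestEzProfile:
    def test_plateau_px_count_matches_conversion(self):
        profile = generate_ez_profile(1024, 2674.9)
        half = (profile.min() + profile.max()) / 2
        run = int((profile >= half).sum())
        assert run == pytest.approx(round(2674.9 / (9000 / 1024)), abs=1)

    def test_zero_width_flat(self):
        assert np.ptp(generate_ez_profile(1024, 0.0)) < 1e-9

    def test_full_scan_width_saturates(self):
        profile = generate_ez_profile(1024, 9000.0)
        assert profile.min() > 60.0 + 0.9 * 100.0

    def test_band_wider_than_scan_rejected(self):
        with pytest.raises(ValueError, match="scan"):
            generate_ez_profile(1024, 9500.0)


class TestCohort:
    def test_table_only_calibration(self):
        """Drawn baselines, rates and correlations match the configured model."""
        n = 1500
        tab = generate_cohort(CohortSpec(n_eyes=n, rng_seed=42))
        se_mean = 11.1 / np.sqrt(n)
        assert tab["pd_scp_v1"].mean() == pytest.approx(33.4, abs=3 * se_mean)
        assert tab["pd_scp_v1"].std() == pytest.approx(11.1, rel=0.08)
        rate_sd = 0.62 * np.sqrt(28)
        assert tab["pd_scp_rate"].mean() == pytest.approx(
            -2.42, abs=3 * rate_sd / np.sqrt(n)
        )
        assert tab["faz_scp_rate"].mean() == pytest.approx(
            0.078, abs=3 * 0.021 * np.sqrt(28) / np.sqrt(n)
        )
        r = np.corrcoef(tab["ez_um_v1"], tab["pd_scp_v1"])[0, 1]
        assert r == pytest.approx(0.660, abs=3 * (1 - 0.660**2) / np.sqrt(n))
        assert (tab["dt_years"] >= 0.5).all()

    def test_zero_rates_freeze_visit_two(self):
        cs = CohortSpec(n_eyes=20, rng_seed=1)
        for name, m in cs.metrics.items():
            cs.metrics[name] = type(m)(
                m.baseline_mean, m.baseline_sd, 0.0, 0.0, m.lo, m.hi
            )
        tab = generate_cohort(cs)
        for name in cs.metrics:
            assert np.array_equal(tab[f"{name}_v1"], tab[f"{name}_v2"])

    def test_table_determinism(self):
        t1 = generate_cohort(CohortSpec(n_eyes=50, rng_seed=9))
        t2 = generate_cohort(CohortSpec(n_eyes=50, rng_seed=9))
        pd.testing.assert_frame_equal(t1, t2)

    def test_non_psd_correlation_rejected(self):
        bad = np.array(
            [
                [1.0, 0.99, -0.99],
                [0.99, 1.0, 0.99],
                [-0.99, 0.99, 1.0],
            ]
        )
        corr = np.eye(7)
        corr[:3, :3] = bad
        with pytest.raises(ValueError, match="positive semidefinite"):
            CohortSpec(corr=corr)

    def test_single_eye_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            CohortSpec(n_eyes=1)

    def test_image_cohort_writes_consistent_truth(self, tmp_path):
        cs = CohortSpec(n_eyes=2, rng_seed=12)
        truth = generate_cohort(cs, out_dir=tmp_path)
        pngs = list(tmp_path.glob("*.png"))
        assert len(pngs) == 2 * 2 * 3  # eyes × visits × (scp, dcp, cc)
        assert len(list(tmp_path.glob("*_ez.csv"))) == 4
        assert (tmp_path / "truth.csv").exists()
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "config.yaml").exists()
        for name in ("pd_scp", "faz_dcp", "ez_um"):
            implied = (truth[f"{name}_v2"] - truth[f"{name}_v1"]) / truth["dt_years"]
            assert np.allclose(truth[f"{name}_rate"], implied)


class TestSampleBivariate:
    def test_large_sample_correlation(self):
        x, y = sample_bivariate(5000, 0.0, 1.0, 0.0, 1.0, 0.66, seed=8)
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.66, abs=0.02)

    def test_marginals(self):
        x, y = sample_bivariate(20000, 2674.9, 1766.8, 33.4, 11.1, 0.5, seed=2)
        assert x.mean() == pytest.approx(2674.9, abs=3 * 1766.8 / np.sqrt(20000))
        assert y.std() == pytest.approx(11.1, rel=0.05)

    def test_degenerate_rho_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            sample_bivariate(10, 0, 1, 0, 1, 1.0, seed=0)
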