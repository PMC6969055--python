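"""Contamination mixture estimator: likelihood components, profile, fitting."""

import numpy as np
import pytest
from scipy import stats

from conmixmr import (
    ContaminationMixture,
    EstimationError,
    MRInputError,
    SummarySet,
    component_logliks,
    conmix_estimate,
    default_psi,
    ivw_estimate,
    overdispersion_phi,
    profile_loglik,
    ratio_estimates,
)

from conftest import random_summary_set, two_cluster_summary


def ratios_from(theta_hat, se_theta):
    j = len(theta_hat)
    ss = SummarySet(
        tuple(f"v{i}" for i in range(j)),
        np.ones(j),
        np.full(j, 0.01),
        np.asarray(theta_hat, float),
        np.asarray(se_theta, float),
    )
    return ratio_estimates(ss)


def brute_force_profile(theta, ratios, psi):
    """Exhaustive maximization over all 2^J validity configurations."""
    lv, lf = component_logliks(theta, ratios, psi)
    j = len(lv)
    configs = ((np.arange(2**j)[:, None] >> np.arange(j)) & 1).astype(float)
    values = configs @ lv + (1.0 - configs) @ lf
    return values.max()


class TestComponents:
    def test_valid_contribution_peaks_at_mode_density(self):
        r = ratios_from([0.5], [0.1])
        lv, _ = component_logliks(0.5, r, psi=1.0)
        assert lv[0] == pytest.approx(-np.log(0.1 * np.sqrt(2 * np.pi)))

    def test_components_match_normal_density_oracle(self):
        r = ratios_from([0.5], [0.1])
        lv, lf = component_logliks(0.0, r, psi=1.0)
        assert lv[0] == pytest.approx(stats.norm.logpdf(0.5, loc=0.0, scale=0.1))
        assert lf[0] == pytest.approx(
            stats.norm.logpdf(0.5, loc=0.0, scale=np.hypot(1.0, 0.1))
        )

    def test_small_psi_limit_recovers_valid_density_at_zero(self):
        r = ratios_from([0.0], [0.2])
        lv, lf = component_logliks(0.0, r, psi=1e-9)
        assert lf[0] == pytest.approx(lv[0], rel=1e-9)

    def test_invalid_inputs_rejected(self):
        r = ratios_from([0.5], [0.1])
        with pytest.raises(MRInputError):
            component_logliks(np.inf, r, psi=1.0)
        with pytest.raises(MRInputError):
            component_logliks(0.0, r, psi=-1.0)


class TestProfile:
    def test_single_variant_valid_at_its_estimate(self):
        r = ratios_from([0.8], [0.05])
        value, zeta = profile_loglik(0.8, r, psi=10.0)
        assert zeta.tolist() == [1]
        assert value == pytest.approx(-np.log(0.05 * np.sqrt(2 * np.pi)))

    def test_all_invalid_when_estimates_near_zero_but_far_from_theta(self):
        r = ratios_from([0.01, -0.02, 0.015], [0.05, 0.05, 0.05])
        _, zeta = profile_loglik(5.0, r, psi=1.0)
        assert zeta.tolist() == [0, 0, 0]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        j = 8
        r = ratios_from(rng.normal(0, 1, j), rng.uniform(0.05, 0.5, j))
        psi = rng.uniform(0.3, 2.0)
        for theta in rng.normal(0, 1.5, 5):
            value, _ = profile_loglik(theta, r, psi)
            assert value == pytest.approx(brute_force_profile(theta, r, psi), abs=1e-10)


class TestDefaultPsi:
    def test_two_point_closed_form(self):
        assert default_psi(ratios_from([0.0, 2.0], [0.1, 0.1])) == pytest.approx(
            1.5 * np.sqrt(2.0)
        )

    def test_degenerate_spread_rejected(self):
        with pytest.raises(MRInputError, match="zero spread"):
            default_psi(ratios_from([1.0, 1.0, 1.0], [0.1, 0.1, 0.1]))
        with pytest.raises(MRInputError, match="at least 2"):
            default_psi(ratios_from([1.0], [0.1]))

    def test_monte_carlo_scale(self):
        rng = np.random.default_rng(5)
        r = ratios_from(rng.normal(0, 1, 100), np.full(100, 0.1))
        assert default_psi(r) == pytest.approx(1.5, abs=0.35)


class TestOverdispersion:
    def make_valid_data(self, phi_true, seed=0, j=200, theta=0.5):
        rng = np.random.default_rng(seed)
        bx = rng.uniform(0.05, 0.15, j)
        se_y = np.full(j, 0.02)
        by = theta * bx + rng.normal(0, phi_true * se_y)
        return SummarySet(
            tuple(f"v{i}" for i in range(j)), bx, np.full(j, 0.002), by, se_y
        )

    def test_exact_fit_floors_to_one(self):
        bx = np.array([0.05, 0.08, 0.1, 0.12])
        ss = SummarySet(("a", "b", "c", "d"), bx, bx * 0 + 0.005, 0.5 * bx, bx * 0 + 0.02)
        assert overdispersion_phi(ss, np.ones(4, bool)) == 1.0
        assert overdispersion_phi(ss, np.ones(4, bool), floor=False) == pytest.approx(
            0.0, abs=1e-12
        )

    @pytest.mark.parametrize("phi_true, expect", [(1.0, 1.0), (2.0, 2.0)])
    def test_recovers_noise_inflation(self, phi_true, expect):
        ss = self.make_valid_data(phi_true)
        phi = overdispersion_phi(ss, np.ones(len(ss), bool), floor=False)
        assert phi == pytest.approx(expect, abs=0.25)

    def test_few_valid_variants_fall_back_to_one(self, caplog):
        ss = self.make_valid_data(2.0, j=5)
        flags = np.array([1, 1, 0, 0, 0], bool)
        with caplog.at_level("WARNING"):
            assert overdispersion_phi(ss, flags) == 1.0
        assert "insufficient" in caplog.text

    def test_no_valid_variants_rejected(self):
        ss = self.make_valid_data(1.0, j=4)
        with pytest.raises(MRInputError):
            overdispersion_phi(ss, np.zeros(4, bool))


class TestFit:
    def test_exact_consensus(self):
        j = 6
        ss = SummarySet(
            tuple(f"v{i}" for i in range(j)),
            np.ones(j),
            np.full(j, 0.01),
            np.full(j, 0.5),
            np.full(j, 0.02),
        )
        res = conmix_estimate(ss, psi=10.0)
        assert res.estimate == pytest.approx(0.5, abs=res.grid_step)
        assert len(res.ci_ranges) == 1
        assert res.covers(0.5)
        assert res.valid_flags.tolist() == [1] * j
        assert res.phi_hat == 1.0

    def test_result_invariants(self, bimodal_data):
        res = conmix_estimate(bimodal_data, psi=0.8)
        grid, ll = res.loglik_curve
        # estimate is the curve argmax and lies inside one CI component
        assert res.estimate == pytest.approx(grid[np.argmax(ll)])
        assert res.covers(res.estimate)
        # components are ordered and disjoint
        for (lo1, hi1), (lo2, hi2) in zip(res.ci_ranges, res.ci_ranges[1:]):
            assert hi1 < lo2
        assert res.phi_hat >= 1.0

    def test_bimodal_two_components_and_modes(self, bimodal_data, unimodal_data):
        res = conmix_estimate(bimodal_data, psi=0.8)
        assert len(res.modes) == 2
        assert len(res.ci_ranges) == 2
        assert res.modes[0] == pytest.approx(0.67, abs=0.02)
        assert res.modes[1] == pytest.approx(0.93, abs=0.02)
        uni = conmix_estimate(unimodal_data, psi=0.8)
        assert len(uni.modes) == 1
        assert len(uni.ci_ranges) == 1

    def test_ivw_limit_under_huge_psi(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            ss = random_summary_set(rng)
            res = conmix_estimate(ss, psi=1e6)
            ivw = ivw_estimate(ss, model="fixed")
            assert res.estimate == pytest.approx(ivw.estimate, abs=res.grid_step)
            assert res.valid_flags.all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sign_equivariance(self, seed):
        ss = random_summary_set(np.random.default_rng(seed))
        res = conmix_estimate(ss, psi=1.0)
        neg = SummarySet(ss.variant_ids, ss.beta_x, ss.se_x, -ss.beta_y, ss.se_y)
        res_neg = conmix_estimate(neg, psi=1.0)
        assert res_neg.estimate == pytest.approx(-res.estimate, abs=1e-12)
        mirrored = sorted([(-hi, -lo) for lo, hi in res_neg.ci_ranges])
        for (lo1, hi1), (lo2, hi2) in zip(mirrored, res.ci_ranges):
            assert lo1 == pytest.approx(lo2, abs=1e-12)
            assert hi1 == pytest.approx(hi2, abs=1e-12)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_scale_equivariance(self, seed):
        c = 2.5
        ss = random_summary_set(np.random.default_rng(seed))
        res = conmix_estimate(ss, psi=1.0)
        scaled = SummarySet(ss.variant_ids, ss.beta_x, ss.se_x, c * ss.beta_y, c * ss.se_y)
        res_c = conmix_estimate(scaled, psi=c * 1.0)
        assert res_c.estimate == pytest.approx(c * res.estimate, abs=1e-9)
        for (lo1, hi1), (lo2, hi2) in zip(res_c.ci_ranges, res.ci_ranges):
            assert lo1 == pytest.approx(c * lo2, abs=1e-9)
            assert hi1 == pytest.approx(c * hi2, abs=1e-9)

    def test_profile_curve_is_continuous(self, bimodal_data):
        """No jumps at validity switch points: adjacent grid values differ by
        at most the maximal gradient of the active branch times the step."""
        res = conmix_estimate(bimodal_data, psi=0.8)
        grid, ll = res.loglik_curve
        step = res.grid_step
        r = res.model.ratios
        grad_bound = np.sum(
            np.maximum(
                np.abs(grid[0] - r.theta_hat), np.abs(grid[-1] - r.theta_hat)
            )
            / r.se_theta**2
        )
        assert np.max(np.abs(np.diff(ll))) <= 1.5 * grad_bound * step

    def test_overdispersion_widens_but_does_not_move_estimate(self):
        rng = np.random.default_rng(21)
        j = 40
        bx = rng.uniform(0.05, 0.15, j)
        by = 0.3 * bx + rng.normal(0, 2 * 0.02, j)  # overdispersed
        ss = SummarySet(
            tuple(f"v{i}" for i in range(j)), bx, np.full(j, 0.002), by, np.full(j, 0.02)
        )
        # psi far above the data scale keeps every variant valid, so the
        # excess spread lands in phi instead of in invalidity calls
        res_on = conmix_estimate(ss, psi=50.0, overdispersion=True)
        res_off = conmix_estimate(ss, psi=50.0, overdispersion=False)
        assert res_on.phi_hat > 1.0
        assert res_off.phi_hat == 1.0
        assert res_on.estimate == res_off.estimate
        np.testing.assert_array_equal(res_on.valid_flags, res_off.valid_flags)
        width = lambda r: sum(hi - lo for lo, hi in r.ci_ranges)
        assert width(res_on) > width(res_off)

    def test_user_grid_not_covering_estimates_warns(self, unimodal_data):
        """A user grid missing the plausible range of the precise estimates
        pins the maximum to a boundary and is flagged, not silently fixed."""
        with pytest.warns(UserWarning, match="does not cover|boundary"):
            res = conmix_estimate(unimodal_data, psi=0.8, grid_min=0.6, grid_max=0.65)
        assert res.estimate == pytest.approx(0.65)

    def test_grid_far_from_all_data_degrades_gracefully(self, unimodal_data):
        """If every variant is invalid everywhere on the grid, the profile is
        flat: the tie-break picks the theta nearest zero, phi stays 1 and the
        whole grid is covered."""
        with pytest.warns(UserWarning, match="does not cover"):
            res = conmix_estimate(unimodal_data, psi=0.8, grid_min=-0.1, grid_max=0.1)
        assert res.estimate == pytest.approx(0.0, abs=res.grid_step)
        assert res.n_valid == 0
        assert res.phi_hat == 1.0
        assert res.covers(0.1) and res.covers(-0.1)

    def test_uninformative_outlier_does_not_degrade_grid(self, unimodal_data):
        """A variant with a near-null exposure association (huge, useless
        ratio estimate) must not stretch the default grid."""
        ss = unimodal_data
        with_outlier = SummarySet(
            ss.variant_ids + ("weak",),
            np.append(ss.beta_x, 1e-4),
            np.append(ss.se_x, 0.01),
            np.append(ss.beta_y, 0.02),
            np.append(ss.se_y, 0.02),
        )
        res = conmix_estimate(with_outlier, psi=0.8)
        clean = conmix_estimate(ss, psi=0.8)
        assert res.grid_step < 5 * clean.grid_step
        assert res.estimate == pytest.approx(clean.estimate, abs=0.01)

    def test_config_validation(self, unimodal_data):
        with pytest.raises(MRInputError):
            ContaminationMixture(unimodal_data, psi=-1.0)
        with pytest.raises(MRInputError):
            ContaminationMixture(unimodal_data, grid_points=50)
        with pytest.raises(MRInputError):
            ContaminationMixture(unimodal_data, alpha=1.5)
        with pytest.raises(MRInputError):
            ContaminationMixture(unimodal_data, grid_min=1.0, grid_max=0.0)

    def test_summary_and_plot_smoke(self, bimodal_data):
        import matplotlib

        matplotlib.use("Agg")
        res = conmix_estimate(bimodal_data, psi=0.8)
        text = res.summary()
        assert "confidence set" in text and "disjoint" in text
        ax = res.plot_profile()
        assert ax.get_xlabel() == "causal effect"
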