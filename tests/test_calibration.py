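"""Evidence scale, prior, local lr+, thresholds, bootstrap and assignment."""

import math

import numpy as np
import pytest

import mavecal.calibration as cal
from mavecal.calibration import (
    CalibrationFailureError,
    CalibrationResult,
    EvidenceCombination,
    EvidenceScale,
    assign_evidence,
    bootstrap_calibrate,
    estimate_prior,
    local_lr_plus,
    log_local_lr_plus,
    modal_points,
    oob_assign,
    posterior,
    solve_c,
    thresholds_from_fit,
)
from mavecal.distributions import SkewNormalParams
from mavecal.mixture import MixtureFit, SampleSet

from helpers import fake_fit_factory as _fake_fit_factory, make_fit




class TestPosterior:
    def test_uninformative_evidence_returns_prior(self):
        for prior in (0.01, 0.1, 0.9):
            assert posterior(1.0, prior) == pytest.approx(prior, rel=1e-12)

    def test_overwhelming_evidence_limit(self):
        assert posterior(1e12, 0.01) == pytest.approx(1.0, abs=1e-9)

    def test_six_points_at_c350(self):
        # one strong + one moderate: posterior odds = 350^(6/8) / 9 ~ 9
        assert posterior(350.4667 ** 0.75, 0.1) == pytest.approx(0.900, abs=0.002)

    def test_strictly_increasing(self):
        lrs = np.linspace(0.1, 50, 100)
        values = posterior(lrs, 0.2)
        assert np.all(np.diff(values) > 0)

    def test_point_composition_is_multiplicative(self):
        # eight supporting lines carry exactly one very-strong line's LR+
        c = 350.0
        assert (c ** (1 / 8)) ** 8 == pytest.approx(c ** 1, rel=1e-12)
        assert posterior((c ** (1 / 8)) ** 8, 0.1) == pytest.approx(
            posterior(c, 0.1), abs=1e-12
        )


class TestSolveC:
    def test_invalid_prior_rejected(self):
        for prior in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                solve_c(prior)

    def test_single_rule_closed_form(self):
        # one strong + one moderate => likely pathogenic at 0.90:
        # c^(3/4) * prior-odds = 9  =>  c = (9 / prior-odds)^(4/3)
        prior = 0.1
        rules = [EvidenceCombination(0, 1, 1, 0, 0.90)]
        prior_odds = prior / (1 - prior)
        expected = (9.0 / prior_odds) ** (4.0 / 3.0)
        assert solve_c(prior, rules) == pytest.approx(expected, rel=1e-4)

    def test_paper_worked_examples(self):
        assert solve_c(0.1) == pytest.approx(350, rel=0.02)
        assert solve_c(0.044) == pytest.approx(1124, rel=0.02)

    def test_all_rules_satisfied_at_solution(self):
        c = solve_c(0.05)
        for rule in cal.DEFAULT_RULES:
            assert posterior(c ** (rule.points / 8), 0.05) >= rule.target_posterior - 1e-9


class TestPrior:
    def test_direct_arithmetic(self):
        est = estimate_prior(make_fit(wp=0.8, wb=0.1, wg=0.17))
        assert est.valid
        assert est.value == pytest.approx(0.1, rel=1e-12)

    def test_boundaries_invalid(self):
        assert not estimate_prior(make_fit(wp=0.8, wb=0.1, wg=0.1)).valid  # prior 0
        assert not estimate_prior(make_fit(wp=0.8, wb=0.1, wg=0.8)).valid  # prior 1

    def test_wp_not_above_wb_invalid(self):
        est = estimate_prior(make_fit(wp=0.1, wb=0.1, wg=0.1))
        assert not est.valid and math.isnan(est.value)

    def test_generator_truth_is_exact(self):
        # inverting w_G = prior*w_P + (1-prior)*w_B is an algebraic identity
        prior, wp, wb = 0.3, 0.7, 0.04
        wg = prior * wp + (1 - prior) * wb
        est = estimate_prior(make_fit(wp=wp, wb=wb, wg=wg))
        assert est.value == pytest.approx(prior, rel=1e-12)


class TestLocalLrPlus:
    def test_equal_weights_give_unity(self):
        fit = make_fit(wp=0.4, wb=0.4)
        np.testing.assert_allclose(local_lr_plus(np.linspace(-6, 3, 50), fit), 1.0)

    def test_identical_components_give_unity(self):
        theta = SkewNormalParams(0, 1, 0.5)
        fit = make_fit(theta_a=theta, theta_n=theta)
        np.testing.assert_allclose(local_lr_plus(np.linspace(-6, 3, 50), fit), 1.0)

    def test_abnormal_tail_limit(self):
        fit = make_fit(wp=0.9, wb=0.05)
        s = fit.theta_abnormal.location - 10 * fit.theta_abnormal.scale
        assert local_lr_plus(s, fit) == pytest.approx(0.9 / 0.05, rel=1e-6)

    def test_log_space_survives_extreme_tails(self):
        fit = make_fit()
        value = log_local_lr_plus(-200.0, fit)
        assert np.isfinite(value)


class TestThresholds:
    def test_gaussian_closed_form(self):
        # pure components (w_P=1, w_B=0) with zero skew: log lr+ is a
        # quadratic in s, so each threshold has a closed form
        theta_a = SkewNormalParams(-4, 0.8, 0)
        theta_n = SkewNormalParams(0, 1.2, 0)
        fit = make_fit(wp=1.0, wb=0.0, wg=0.1, theta_a=theta_a, theta_n=theta_n,
                       score_range=(-5.0, 2.0))
        scale = EvidenceScale(c=350.0, prior=0.1)
        result = thresholds_from_fit(fit, scale)
        for level, threshold in result.pathogenic_thresholds.items():
            floor = (level / 8) * math.log(350.0)
            # log ratio = log(sn/sa scales) - (s-mu_a)^2/(2 w_a^2) + (s-mu_n)^2/(2 w_n^2)
            a = -1 / (2 * 0.8**2) + 1 / (2 * 1.2**2)
            b = (-4) / 0.8**2 - 0 / 1.2**2
            const = math.log(1.2 / 0.8) - 4**2 / (2 * 0.8**2) + 0 / (2 * 1.2**2)
            roots = np.roots([a, b, const - floor])
            root = min(r.real for r in roots if abs(r.imag) < 1e-9 and -5 <= r.real <= 2.5)
            assert threshold == pytest.approx(root, abs=1e-6)

    def test_unreachable_levels_absent(self):
        # nearly equal weights: lr+ barely moves off 1, no floor is met
        fit = make_fit(wp=0.051, wb=0.05, wg=0.0503)
        result = thresholds_from_fit(fit, EvidenceScale(c=350.0, prior=0.1))
        assert result.pathogenic_thresholds == {}
        assert result.benign_thresholds == {}

    def test_wp_below_wb_rejected(self):
        with pytest.raises(ValueError):
            thresholds_from_fit(make_fit(wp=0.05, wb=0.1), EvidenceScale(c=350, prior=0.1))

    def test_threshold_ordering(self, recovery_fits):
        for _, _, model in recovery_fits[:5]:
            prior = estimate_prior(model)
            scale = EvidenceScale(c=solve_c(prior.value), prior=prior.value)
            result = thresholds_from_fit(model, scale)
            path = result.pathogenic_thresholds
            for weak, strong in [(1, 2), (2, 3), (3, 4), (4, 8)]:
                if weak in path and strong in path:
                    assert path[strong] <= path[weak] + 1e-9
            ben = result.benign_thresholds
            for weak, strong in [(-1, -2), (-2, -3), (-3, -4), (-4, -8)]:
                if weak in ben and strong in ben:
                    assert ben[strong] >= ben[weak] - 1e-9


class TestAssignEvidence:
    RESULT = CalibrationResult(
        prior=0.1,
        c=350.0,
        pathogenic_thresholds={8: -4.0, 4: -3.0, 2: -2.5, 1: -2.0},
        benign_thresholds={-1: -0.5, -4: 0.5},
    )

    def test_strongest_pathogenic_level_wins(self):
        assert assign_evidence(-5.0, self.RESULT) == 8
        assert assign_evidence(-2.7, self.RESULT) == 2

    def test_indeterminate_band(self):
        assert assign_evidence(-1.0, self.RESULT) == 0

    def test_strongest_benign_level_wins(self):
        assert assign_evidence(1.0, self.RESULT) == -4
        assert assign_evidence(0.0, self.RESULT) == -1

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            assign_evidence(float("nan"), self.RESULT)

    def test_monotone_in_score(self):
        sweep = np.linspace(-6, 2, 1000)
        points = [assign_evidence(s, self.RESULT) for s in sweep]
        assert np.all(np.diff(points) <= 0)


class TestModalPoints:
    def test_constant_votes(self):
        assert modal_points([4, 4, 4]) == 4

    def test_tie_breaks_toward_zero(self):
        assert modal_points([4] * 10 + [-1] * 10) == -1
        assert modal_points([2] * 3 + [1] * 3) == 1

    def test_matches_brute_force_counter(self):
        votes = [1, 1, 2, 2, 2]
        counts = {v: votes.count(v) for v in set(votes)}
        assert counts[modal_points(votes)] == max(counts.values())




@pytest.fixture
def small_samples():
    rng = np.random.default_rng(0)
    return SampleSet(
        scores_plp=rng.normal(-3, 1, 40),
        scores_blb=rng.normal(0, 1, 40),
        scores_ref=rng.normal(-0.4, 1.2, 60),
    )


class TestBootstrap:
    def test_degenerate_bootstrap_equals_point_estimate(self, small_samples):
        summary = bootstrap_calibrate(
            small_samples, n_boot=1, n_restarts=3, seed=0, resample=False
        )
        from mavecal.mixture import fit as fit_mixture

        model = fit_mixture(small_samples, n_restarts=3, seed=0)
        prior = estimate_prior(model)
        scale = EvidenceScale(c=solve_c(prior.value), prior=prior.value)
        point = thresholds_from_fit(model, scale)
        expected = {**point.pathogenic_thresholds, **point.benign_thresholds}
        assert summary.final_thresholds == expected
        assert summary.valid_iterations == 1

    def test_invalid_priors_excluded_and_counted(self, small_samples, monkeypatch):
        # alternate valid / invalid (w_P <= w_B) fits
        monkeypatch.setattr(
            cal, "fit_mixture", _fake_fit_factory([(0.9, 0.05, 0.135), (0.1, 0.5, 0.3)])
        )
        summary = bootstrap_calibrate(small_samples, n_boot=6, n_restarts=1, seed=0)
        assert summary.n_iterations == 6
        assert summary.valid_iterations == 3
        assert np.isnan(summary.per_iteration_priors).sum() == 3

    def test_all_invalid_raises(self, small_samples, monkeypatch):
        monkeypatch.setattr(cal, "fit_mixture", _fake_fit_factory([(0.1, 0.5, 0.3)]))
        with pytest.raises(CalibrationFailureError):
            bootstrap_calibrate(small_samples, n_boot=3, n_restarts=1, seed=0)

    def test_reach_rule_gates_reporting(self, small_samples, monkeypatch):
        # 9 of 10 valid iterations reach the strong levels; reach 0.9 < 0.95
        specs = [(0.9, 0.05, 0.135)] * 9 + [(0.0505, 0.05, 0.05025)]
        monkeypatch.setattr(cal, "fit_mixture", _fake_fit_factory(specs))
        summary = bootstrap_calibrate(small_samples, n_boot=10, n_restarts=1, seed=0)
        assert summary.valid_iterations == 10
        for level, reach in summary.reach_fraction.items():
            if reach < 0.95:
                assert level not in summary.final_thresholds
            else:
                assert level in summary.final_thresholds

    def test_saturated_level_reach_is_one(self, monkeypatch, small_samples):
        # extreme separation: every level's floor is met at the low extreme
        monkeypatch.setattr(cal, "fit_mixture", _fake_fit_factory([(1.0, 0.001, 0.1)]))
        summary = bootstrap_calibrate(small_samples, n_boot=5, n_restarts=1, seed=0)
        assert summary.reach_fraction[8] == 1.0

    def test_percentile_aggregation(self, small_samples, monkeypatch):
        monkeypatch.setattr(
            cal,
            "fit_mixture",
            _fake_fit_factory([(0.9, 0.05, 0.135), (0.85, 0.04, 0.12), (0.95, 0.06, 0.15)]),
        )
        summary = bootstrap_calibrate(small_samples, n_boot=9, n_restarts=1, seed=0)
        for level, final in summary.final_thresholds.items():
            vals = summary.per_iteration_thresholds[level]
            vals = vals[~np.isnan(vals)]
            q = 5 if level > 0 else 95
            assert final == pytest.approx(np.percentile(vals, q))


class TestOutOfBag:
    def test_counting_oracle_on_toy_trace(self, small_samples):
        summary = bootstrap_calibrate(small_samples, n_boot=5, n_restarts=2, seed=3)
        variants = [("P", 0, -4.0), ("B", 3, 0.5), ("G", 10, -1.2)]
        results = oob_assign(variants, summary)
        valid = ~np.isnan(summary.per_iteration_priors)
        for (key, idx, score), got in zip(variants, results):
            votes = []
            for i in range(summary.n_iterations):
                if not valid[i] or idx in summary.memberships[i][key]:
                    continue
                path, ben = {}, {}
                for lv in summary.points_levels:
                    t = summary.per_iteration_thresholds[lv][i]
                    if not np.isnan(t):
                        path[lv] = t
                    t = summary.per_iteration_thresholds[-lv][i]
                    if not np.isnan(t):
                        ben[-lv] = t
                met = [lv for lv, t in path.items() if score <= t]
                if met:
                    votes.append(max(met))
                else:
                    met = [lv for lv, t in ben.items() if score >= t]
                    votes.append(min(met) if met else 0)
            if votes:
                counts = {v: votes.count(v) for v in set(votes)}
                assert got is not None
                assert counts[got] == max(counts.values())
            else:
                assert got is None

    def test_always_in_bag_yields_none(self, small_samples):
        summary = bootstrap_calibrate(small_samples, n_boot=2, n_restarts=2, seed=1,
                                      resample=False)
        assert oob_assign([("P", 0, -4.0)], summary) == [None]
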