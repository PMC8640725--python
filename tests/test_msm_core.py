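"""Multistate model: likelihoods, fitting, probabilities, sojourns."""

import numpy as np
import pytest

from mmtraj import (
    exact_path_loglik,
    fit,
    hazard_ratios,
    make_intensity_matrix,
    model_from_rates,
    panel_loglik,
    sojourn_times,
    transition_probability,
)
from mmtraj.cohort import simulate_cohort
from mmtraj.covariates import encode_cohort
from mmtraj.msm import (
    FitResult,
    one_year_report,
    panel_observations_from_history,
    render_one_in,
)
from mmtraj.state_builder import StateHistory, build_cohort_histories
from mmtraj.states import DEATH, N_STATES, TRANSITIONS

from .conftest import RECOVERY_BASELINES, recovery_config


def random_valid_q(rng, lo=0.02, hi=0.9):
    rates = dict(zip(TRANSITIONS, rng.uniform(lo, hi, len(TRANSITIONS))))
    return model_from_rates(rates).intensity_matrix()


class TestIntensityMatrix:
    def test_zero_coefficients_reproduce_baselines(self):
        model = model_from_rates(
            {(0, 1): 0.2, (1, 2): 0.1}, covariate_names=("z",)
        )
        Q = make_intensity_matrix(model, np.array([1.0]))
        assert Q[0, 1] == pytest.approx(0.2)
        assert Q[1, 2] == pytest.approx(0.1)

    def test_hazard_ratio_multiplies_rate(self):
        model = model_from_rates(
            {(0, 1): 0.2}, {(0, 1): {"z": 1.5}}, ("z",)
        )
        assert make_intensity_matrix(model, np.array([1.0]))[0, 1] == pytest.approx(0.3)
        assert make_intensity_matrix(model, np.array([0.0]))[0, 1] == pytest.approx(0.2)

    def test_rows_sum_to_zero_and_death_absorbing(self, rng):
        for _ in range(20):
            Q = random_valid_q(rng)
            assert np.abs(Q.sum(axis=1)).max() < 1e-12
            assert np.all(Q[DEATH] == 0.0)


class TestExactLoglik:
    def test_censored_sojourn_closed_form(self):
        # single sojourn in S0 of length T; total exit rate lambda
        a, b, T = 0.3, 0.04, 2.5
        Q = model_from_rates({(0, 1): a, (0, 4): b}).intensity_matrix()
        h = StateHistory("p", [(0.0, 0)], T, True, 0, 0)
        assert exact_path_loglik(h, Q) == pytest.approx(-(a + b) * T, abs=1e-12)

    def test_one_transition_closed_form(self):
        # S0 -> S1 at time s, censored at T:
        # loglik = -(a+b)s + log a - c(T-s), c = total exit rate from S1
        a, b, s, T = 0.3, 0.05, 1.2, 4.0
        c1, c2, c3 = 0.1, 0.2, 0.02
        Q = model_from_rates(
            {(0, 1): a, (0, 4): b, (1, 0): c1, (1, 2): c2, (1, 4): c3}
        ).intensity_matrix()
        c = c1 + c2 + c3
        h = StateHistory("p", [(0.0, 0), (s, 1)], T, True, 0, 1)
        expected = -(a + b) * s + np.log(a) - c * (T - s)
        assert exact_path_loglik(h, Q) == pytest.approx(expected, abs=1e-12)

    def test_death_transition_contributes_log_rate(self):
        lam, mu, td = 0.2, 0.05, 3.0
        Q = model_from_rates({(0, 1): lam, (0, 4): mu}).intensity_matrix()
        h = StateHistory("p", [(0.0, 0), (td, DEATH)], td, False, 0, 0)
        assert exact_path_loglik(h, Q) == pytest.approx(
            -(lam + mu) * td + np.log(mu), abs=1e-12
        )

    def test_zero_rate_transition_signals_minus_inf(self):
        Q = model_from_rates({(0, 4): 0.5}).intensity_matrix()
        h = StateHistory("p", [(0.0, 0), (1.0, 1)], 2.0, True, 0, 1)
        assert exact_path_loglik(h, Q) == -np.inf

    def test_cohort_loglik_is_sum_of_patient_logliks(self):
        cfg = recovery_config(200, seed=13)
        patients, events = simulate_cohort(cfg)
        histories = build_cohort_histories(patients, events)
        X = encode_cohort(patients, ("female",))
        res = fit(histories, X, ("female",))
        total = sum(
            exact_path_loglik(h, res.model.intensity_matrix(x))
            for h, x in zip(histories, X)
        )
        assert res.loglik == pytest.approx(total, rel=1e-9)


class TestPanelLoglik:
    def test_same_state_zero_rates_probability_one(self):
        Q = np.zeros((N_STATES, N_STATES))
        assert panel_loglik([(0.0, 1), (2.0, 1)], Q) == 0.0

    def test_zero_time_state_change_rejected(self):
        Q = model_from_rates({(0, 1): 0.5}).intensity_matrix()
        with pytest.raises(ValueError, match="identical times"):
            panel_loglik([(1.0, 0), (1.0, 1)], Q)

    def test_dense_limit_matches_exact_on_toy(self):
        """Dense snapshots converge to the exact likelihood on paths whose
        only jump is the exactly-timed death (|diff| < 1e-3 at dt=0.001)."""
        Q = model_from_rates(
            {(0, 1): 0.3, (1, 0): 0.1, (0, 4): 0.04, (1, 4): 0.06}
        ).intensity_matrix()
        grid = np.round(np.arange(0.0, 3.0, 0.001), 9)

        h_cens = StateHistory("c", [(0.0, 1)], 3.0, True, 1, 1)
        obs = panel_observations_from_history(h_cens, extra_times=grid)
        assert abs(panel_loglik(obs, Q) - exact_path_loglik(h_cens, Q)) < 1e-3

        h_dead = StateHistory("d", [(0.0, 0), (3.0, DEATH)], 3.0, False, 0, 0)
        obs = panel_observations_from_history(h_dead, extra_times=grid)
        assert abs(panel_loglik(obs, Q) - exact_path_loglik(h_dead, Q)) < 1e-3


class TestFit:
    def test_baseline_recovery_within_three_se(self):
        cfg = recovery_config(1500, seed=17)
        patients, events = simulate_cohort(cfg)
        histories = build_cohort_histories(patients, events)
        res = fit(histories)
        assert res.converged
        for trans in TRANSITIONS:
            est = res.model.baseline_log_rates[trans]
            se = np.sqrt(res.covariance[trans][0, 0])
            assert abs(est - np.log(RECOVERY_BASELINES[trans])) < 3 * se

    def test_matches_statsmodels_poisson_glm(self):
        """Independent route: the exact-times likelihood is a Poisson GLM
        with log-exposure offset per transition."""
        import statsmodels.api as sm

        from mmtraj.msm import sufficient_stats

        cfg = recovery_config(800, seed=23)
        patients, events = simulate_cohort(cfg)
        histories = build_cohort_histories(patients, events)
        X = encode_cohort(patients, ("female",))
        res = fit(histories, X, ("female",))
        time_at_risk, counts = sufficient_stats(histories)
        for trans in [(0, 1), (1, 2), (3, 4)]:
            r = trans[0]
            T, d = time_at_risk[:, r], counts[trans]
            keep = T > 0
            glm = sm.GLM(
                d[keep],
                sm.add_constant(X[keep]),
                family=sm.families.Poisson(),
                exposure=T[keep],
            ).fit()
            assert res.model.baseline_log_rates[trans] == pytest.approx(
                glm.params[0], abs=1e-6
            )
            assert res.model.coefficients[trans][0] == pytest.approx(
                glm.params[1], abs=1e-6
            )
            se_ours = np.sqrt(res.covariance[trans][1, 1])
            assert se_ours == pytest.approx(glm.bse[1], rel=1e-4)

    def test_degenerate_single_patient_flags_na(self):
        h = StateHistory("p", [(0.0, 0)], 2.0, True, 0, 0)
        res = fit([h])
        assert set(res.na_transitions) == set(TRANSITIONS)
        hr = hazard_ratios(res)
        assert hr.empty  # no covariates -> no HR rows
        report = one_year_report(res)
        assert report["p_up_or_death_from_S0"] == 0.0
        assert report["p_up_or_death_from_S0_one_in"] == "—"
        assert np.allclose(report["matrix"].P, np.eye(N_STATES))

    def test_zero_event_category_reported_na(self):
        """A covariate category in which no jumps occur gets NA, mirroring
        low-number cells in stratified hazard-ratio tables."""
        cfg = recovery_config(300, seed=31)
        patients, events = simulate_cohort(cfg)
        histories = build_cohort_histories(patients, events)
        X = np.zeros((len(patients), 1))  # dummy never active
        res = fit(histories, X, ("never_active",))
        hr = hazard_ratios(res)
        assert hr["hr"].isna().all()

    def test_exact_and_panel_estimates_agree_on_dense_grid(self):
        cfg = recovery_config(120, seed=37)
        patients, events = simulate_cohort(cfg)
        histories = build_cohort_histories(patients, events)
        exact = fit(histories)
        panel = fit(histories, mode="panel", panel_grid=0.2)
        for trans in TRANSITIONS:
            a = exact.model.baseline_log_rates[trans]
            b = panel.model.baseline_log_rates[trans]
            if np.isnan(a):
                continue
            assert np.exp(b) == pytest.approx(np.exp(a), rel=0.05)

    def test_misaligned_covariates_rejected(self):
        h = StateHistory("p", [(0.0, 0)], 1.0, True, 0, 0)
        with pytest.raises(ValueError, match="align"):
            fit([h], np.zeros((2, 1)), ("z",))


class TestHazardRatios:
    def test_null_and_exact_coefficients(self):
        model = model_from_rates(
            {(0, 1): 0.1, (1, 2): 0.1},
            {(1, 2): {"z": 2.0}},
            ("z",),
        )
        res = FitResult(
            model=model,
            covariance={t: np.zeros((2, 2)) for t in TRANSITIONS},
            param_names={t: ["log_rate", "z"] for t in TRANSITIONS},
            loglik=0.0,
            converged=True,
            n_transitions_observed={t: 1 for t in TRANSITIONS},
        )
        hr = hazard_ratios(res).set_index("transition")
        assert hr.loc["S0->S1", "hr"] == pytest.approx(1.0)
        assert hr.loc["S1->S2", "hr"] == pytest.approx(2.0)
        assert hr.loc["S1->S2", "lo"] == pytest.approx(2.0)
        assert hr.loc["S1->S2", "hi"] == pytest.approx(2.0)

    def test_table_covers_all_ten_transitions(self):
        cfg = recovery_config(400, seed=41)
        patients, events = simulate_cohort(cfg)
        histories = build_cohort_histories(patients, events)
        X = encode_cohort(patients, ("female",))
        hr = hazard_ratios(fit(histories, X, ("female",)))
        labels = {
            "S0->S1", "S1->S2", "S2->S3plus", "S0->Death", "S1->Death",
            "S2->Death", "S3plus->Death", "S1->S0", "S2->S1", "S3plus->S2",
        }
        assert set(hr["transition"]) == labels
        assert len(hr) == 10


class TestTransitionProbability:
    def test_zero_horizon_is_identity(self, rng):
        P = transition_probability(random_valid_q(rng), 0.0).P
        assert np.allclose(P, np.eye(N_STATES), atol=1e-12)

    def test_death_only_closed_form(self):
        Q = model_from_rates({(0, 4): 0.5}).intensity_matrix()
        P = transition_probability(Q, 1.0).P
        assert P[0, DEATH] == pytest.approx(1 - np.exp(-0.5), abs=1e-10)

    def test_chapman_kolmogorov(self, rng):
        for _ in range(50):
            Q = random_valid_q(rng)
            P1 = transition_probability(Q, 1.0).P
            P2 = transition_probability(Q, 2.0).P
            assert np.abs(P1 @ P1 - P2).max() < 1e-8
            assert np.abs(P1.sum(axis=1) - 1).max() < 1e-8

    def test_absorption_probability_monotone_in_time(self, rng):
        for _ in range(20):
            Q = random_valid_q(rng)
            grid = np.linspace(0.0, 5.0, 26)
            pd_ = np.array(
                [transition_probability(Q, t).P[:, DEATH] for t in grid]
            )
            assert np.all(np.diff(pd_, axis=0) >= -1e-10)

    def test_invalid_matrix_rejected(self):
        bad = np.ones((N_STATES, N_STATES))
        with pytest.raises(ValueError, match="invalid"):
            transition_probability(bad, 1.0)
        with pytest.raises(ValueError, match="non-negative"):
            transition_probability(np.zeros((N_STATES, N_STATES)), -1.0)


class TestSojournAndReport:
    def test_exponential_mean(self):
        Q = model_from_rates({(0, 1): 0.5}).intensity_matrix()
        assert sojourn_times(Q)[0] == pytest.approx(2.0)

    def test_no_exit_state_is_infinite(self):
        Q = model_from_rates({(0, 1): 0.5}).intensity_matrix()
        assert np.isinf(sojourn_times(Q)[3])

    def test_empirical_sojourn_matches_negative_inverse_diagonal(self):
        from mmtraj.cohort import simulate_path_q

        Q = model_from_rates(
            {(0, 1): 0.4, (0, 4): 0.1}
        ).intensity_matrix()
        rng = np.random.default_rng(4)
        n = 4000
        sojourns = np.empty(n)
        for i in range(n):
            path = simulate_path_q(Q, 1e6, 0, rng)
            sojourns[i] = path[1][0] if len(path) > 1 else 1e6
        se = sojourns.std(ddof=1) / np.sqrt(n)
        assert abs(sojourns.mean() - (-1.0 / Q[0, 0])) < 3 * se

    def test_one_in_rendering_convention(self):
        assert render_one_in(0.06) == "1 in 17"
        assert render_one_in(0.85) == "1"
        assert render_one_in(0.0) == "—"
        assert render_one_in(0.12) == "1 in 8"

    def test_report_summaries_equal_matrix_cell_sums(self):
        cfg = recovery_config(500, seed=43)
        patients, events = simulate_cohort(cfg)
        histories = build_cohort_histories(patients, events)
        X = encode_cohort(patients, ("female",))
        res = fit(histories, X, ("female",))
        report = one_year_report(res, reference={"female": 1.0})
        P = report["matrix"].P
        assert report["p_up_or_death_from_S0"] == pytest.approx(P[0, 1] + P[0, 4])
        assert report["p_up_or_death_from_S2"] == pytest.approx(P[2, 3] + P[2, 4])
        assert report["sojourn_years"][0] == pytest.approx(
            -1.0 / res.model.intensity_matrix(np.array([1.0]))[0, 0]
        )

    def test_report_rejects_unknown_reference(self):
        h = StateHistory("p", [(0.0, 0)], 1.0, True, 0, 0)
        res = fit([h])
        with pytest.raises(ValueError, match="reference"):
            one_year_report(res, reference={"nonexistent": 1.0})
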