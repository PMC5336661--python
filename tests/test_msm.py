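import numpy as np
import pandas as pd
import pytest
import scipy.linalg
from scipy.integrate import solve_ivp

from cogmsm.msm import (
    MultiStateModel, StructureError, TransitionStructure, build_q,
    four_state_structure, subject_loglik, three_state_structure,
    transition_probability,
)
from cogmsm.panel import CohortPanel
from cogmsm.simulate import SimConfig, simulate_cohort
from cogmsm._linalg import expm_batch

TWO_STATE = TransitionStructure(states=("CN", "DEATH"),
                                transitions=(("CN", "DEATH"),))


def random_q(rng, d=4):
    Q = rng.uniform(0.01, 0.5, size=(d, d))
    Q[-1] = 0.0  # absorbing last state
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


class TestStructure:
    def test_absorbing_states_derived(self):
        st = four_state_structure()
        assert st.absorbing_states == ("DEATH",)
        assert three_state_structure().absorbing_states == ("DEATH",)

    def test_unreachable_state_rejected(self):
        with pytest.raises(StructureError, match="unreachable"):
            TransitionStructure(states=("A", "B", "C"),
                                transitions=(("A", "B"),))

    def test_flat_covariates_attach_to_every_transition(self):
        st = four_state_structure(("adri",))
        assert all(st.covariates[t] == ("adri",) for t in st.transitions)
        assert st.n_states == 4


class TestBuildQ:
    def test_null_covariate_effects_give_baseline(self):
        st = three_state_structure(("x",))
        theta = {t: np.log(0.1) for t in st.transitions}
        beta = {t: {"x": 0.0} for t in st.transitions}
        Q0 = build_q(st, theta)
        Q1 = build_q(st, theta, beta, {"x": 5.0})
        np.testing.assert_allclose(Q0, Q1)

    def test_log_two_coefficient_doubles_one_intensity(self):
        st = three_state_structure()
        theta = {t: np.log(0.1) for t in st.transitions}
        beta = {("CN", "MCI"): {"x": np.log(2.0)}}
        Q = build_q(st, theta, beta, {"x": 1.0})
        assert Q[0, 1] == pytest.approx(0.2)
        assert Q[0, 2] == pytest.approx(0.1)
        np.testing.assert_allclose(Q.sum(axis=1), 0, atol=1e-12)

    def test_disallowed_transitions_exactly_zero(self):
        st = four_state_structure()
        theta = {t: 1.0 for t in st.transitions}
        Q = build_q(st, theta)
        assert Q[st.index("DEMENTIA"), st.index("CN")] == 0.0
        assert Q[st.index("DEMENTIA"), st.index("MCI")] == 0.0
        np.testing.assert_array_equal(Q[st.index("DEATH")], 0.0)

    def test_missing_covariate_raises(self):
        st = three_state_structure()
        theta = {t: 0.0 for t in st.transitions}
        with pytest.raises(KeyError):
            build_q(st, theta, {("CN", "MCI"): {"x": 1.0}}, {})


class TestTransitionProbability:
    def test_zero_time_is_identity(self, rng):
        P = transition_probability(random_q(rng), 0.0)
        np.testing.assert_allclose(P, np.eye(4), atol=1e-12)

    def test_two_state_closed_form(self):
        Q = np.array([[-0.1, 0.1], [0.0, 0.0]])
        P = transition_probability(Q, 4.0)
        assert P[0, 1] == pytest.approx(1 - np.exp(-0.4), abs=1e-10)
        assert P[0, 1] == pytest.approx(0.329680, abs=1e-6)

    def test_negative_time_rejected(self, rng):
        with pytest.raises(ValueError):
            transition_probability(random_q(rng), -1.0)

    def test_chapman_kolmogorov(self, rng):
        for _ in range(10):
            Q = random_q(rng)
            s, t = rng.uniform(0.1, 5, size=2)
            left = scipy.linalg.expm((s + t) * Q)  # independent oracle
            np.testing.assert_allclose(
                transition_probability(Q, s) @ transition_probability(Q, t),
                left, atol=1e-8)

    def test_rows_sum_to_one_entries_in_unit_interval(self, rng):
        for _ in range(10):
            P = transition_probability(random_q(rng), rng.uniform(0, 10))
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert (P > -1e-12).all() and (P < 1 + 1e-12).all()

    def test_batched_exponential_matches_scipy(self, rng):
        A = np.stack([random_q(rng) * rng.uniform(0.1, 8) for _ in range(40)])
        ours = expm_batch(A)
        ref = np.stack([scipy.linalg.expm(a) for a in A])
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_matches_kolmogorov_forward_integration(self, rng):
        # dP/dt = P Q integrated numerically as an independent oracle
        for _ in range(5):
            Q = random_q(rng)
            t = rng.uniform(0.5, 6)
            sol = solve_ivp(lambda _, p: (p.reshape(4, 4) @ Q).ravel(),
                            (0, t), np.eye(4).ravel(), rtol=1e-10, atol=1e-12)
            np.testing.assert_allclose(
                transition_probability(Q, t), sol.y[:, -1].reshape(4, 4), atol=1e-6)


class TestSubjectLoglik:
    theta = {("CN", "DEATH"): np.log(0.1)}

    def test_survival_interval_closed_form(self):
        # staying alive 4 years at hazard 0.1: log e^{-0.4}
        ll = subject_loglik([60, 64], ["CN", "CN"], TWO_STATE, self.theta)
        assert ll == pytest.approx(-0.4, abs=1e-10)

    def test_exact_death_limit_is_log_intensity(self):
        ll = subject_loglik([60, 60 + 1e-9], ["CN", "DEATH"], TWO_STATE, self.theta)
        assert ll == pytest.approx(np.log(0.1), abs=1e-6)

    def test_exact_death_closed_form(self):
        # death at dt: survive then jump, density 0.1 e^{-0.1 dt}
        ll = subject_loglik([60, 63], ["CN", "DEATH"], TWO_STATE, self.theta)
        assert ll == pytest.approx(np.log(0.1) - 0.3, abs=1e-8)

    def test_structurally_impossible_observation_is_minus_inf(self):
        st = TransitionStructure(states=("CN", "MCI", "DEMENTIA"),
                                 transitions=(("CN", "MCI"), ("CN", "DEMENTIA")),
                                 death_state=None)
        theta = {("CN", "MCI"): np.log(0.1), ("CN", "DEMENTIA"): np.log(0.1)}
        # recovery out of dementia is disallowed: observing it has probability 0
        ll = subject_loglik([60, 64], ["DEMENTIA", "CN"], st, theta)
        assert ll == -np.inf

    def test_censored_record_contributes_nothing_by_default(self):
        base = subject_loglik([60, 64], ["CN", "CN"], TWO_STATE, self.theta)
        with_cens = subject_loglik([60, 64, 68], ["CN", "CN", "CENSORED"],
                                   TWO_STATE, self.theta)
        assert with_cens == pytest.approx(base)

    def test_alive_unknown_policy_sums_living_states(self):
        ll = subject_loglik([60, 64], ["CN", "CENSORED"], TWO_STATE, self.theta,
                            censored_policy="alive_unknown")
        assert ll == pytest.approx(-0.4, abs=1e-10)


def two_state_panel(n, lam, seed):
    cfg = SimConfig(n_subjects=n, structure=TWO_STATE,
                    theta={("CN", "DEATH"): np.log(lam)}, beta={},
                    covariates={}, dropout=(0.0, 0.0, 0.0))
    panel, _ = simulate_cohort(cfg, seed=seed)
    keep = panel.observation_counts()
    return CohortPanel(panel.data[panel.data["subject_id"].isin(
        keep[keep >= 2].index)].copy())


class TestFit:
    def test_two_state_mle_matches_events_over_exposure(self):
        # with exactly observed deaths the MLE has the closed form D / exposure
        panel = two_state_panel(1000, 0.05, seed=11)
        deaths, exposure = 0, 0.0
        for _, grp in panel.data.groupby("subject_id"):
            exposure += grp["age"].iloc[-1] - grp["age"].iloc[0]
            deaths += (grp["state"] == "DEATH").any()
        fit = MultiStateModel(panel, TWO_STATE).fit()
        assert np.exp(fit.params[0]) == pytest.approx(deaths / exposure, rel=1e-4)
        # and the estimate is close to the generating hazard
        assert np.exp(fit.params[0]) == pytest.approx(0.05, rel=0.15)

    def test_gradient_vanishes_at_optimum(self):
        panel = two_state_panel(300, 0.05, seed=2)
        model = MultiStateModel(panel, TWO_STATE)
        fit = model.fit()
        h = 1e-5
        x = fit.params.copy()
        g = (model.loglik(x + h) - model.loglik(x - h)) / (2 * h)
        assert abs(g) < 1e-2  # per ~300 subjects: essentially zero slope

    def test_multistart_reaches_same_likelihood(self):
        cfg = SimConfig(n_subjects=300, beta={}, covariates={})
        panel, _ = simulate_cohort(cfg, seed=5)
        panel = CohortPanel(panel.data.groupby("subject_id").filter(
            lambda g: len(g) >= 2))
        model = MultiStateModel(panel, four_state_structure())
        x0 = model.crude_start()
        fit_a = model.fit(start=x0)
        fit_b = model.fit(start=x0 + 0.4)
        assert fit_a.loglik == pytest.approx(fit_b.loglik, abs=1e-4)

    def test_loglik_improves_on_start(self):
        panel = two_state_panel(200, 0.08, seed=9)
        model = MultiStateModel(panel, TWO_STATE)
        x0 = model.crude_start() + 0.7
        fit = model.fit(start=x0)
        assert fit.loglik >= model.loglik(x0)

    def test_single_observation_subject_rejected(self):
        df = pd.DataFrame({"subject_id": ["a"], "wave": [1], "age": [60.0],
                           "state": ["CN"]})
        with pytest.raises(ValueError, match="single observation"):
            MultiStateModel(CohortPanel(df), TWO_STATE)


@pytest.fixture(scope="module")
def fit():
    cfg = SimConfig(n_subjects=400, beta={}, covariates={})
    panel, _ = simulate_cohort(cfg, seed=21)
    panel = CohortPanel(panel.data.groupby("subject_id").filter(
        lambda g: len(g) >= 2))
    return MultiStateModel(panel, four_state_structure()).fit(compute_cov=False)


class TestStateProbabilities:

    def test_zero_horizon_degenerate(self, fit):
        p = fit.state_probability_after(0.0, from_state="CN")
        assert p["CN"] == pytest.approx(1.0, abs=1e-12)

    def test_probabilities_sum_to_one(self, fit):
        for t in (1.0, 4.0, 12.0):
            assert fit.state_probability_after(t).sum() == pytest.approx(1.0, abs=1e-9)

    def test_death_probability_monotone_and_matches_ode(self, fit):
        Q = fit.intensity_matrix()
        grid = np.linspace(0, 12, 13)
        deaths = [fit.state_probability_after(t)["DEATH"] for t in grid]
        assert all(b >= a - 1e-12 for a, b in zip(deaths, deaths[1:]))
        sol = solve_ivp(lambda _, p: p @ Q, (0, 12), np.eye(4)[0],
                        t_eval=grid, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(deaths, sol.y[3], atol=1e-6)


class TestCoverage:
    def test_wald_intervals_cover_truth_at_nominal_rate(self):
        """Two-state model with a covariate: 95% CI coverage over 200 cohorts."""
        true_lam, true_beta = 0.08, np.log(1.5)
        st = TransitionStructure(states=("CN", "DEATH"),
                                 transitions=(("CN", "DEATH"),),
                                 covariates=("x",))
        cover_theta = cover_beta = 0
        n_rep = 200
        for rep in range(n_rep):
            cfg = SimConfig(
                n_subjects=150, structure=st,
                theta={("CN", "DEATH"): np.log(true_lam)},
                beta={("CN", "DEATH"): {"x": true_beta}},
                covariates={"x": {"dist": "normal"}}, dropout=(0, 0, 0))
            panel, _ = simulate_cohort(cfg, seed=1000 + rep)
            keep = panel.observation_counts()
            panel = CohortPanel(panel.data[panel.data["subject_id"].isin(
                keep[keep >= 2].index)].copy())
            fit = MultiStateModel(panel, st).fit()
            se = fit.se
            lo, hi = fit.params - 1.96 * se, fit.params + 1.96 * se
            cover_theta += lo[0] <= np.log(true_lam) <= hi[0]
            cover_beta += lo[1] <= true_beta <= hi[1]
        # binomial(200, .95): 3 SD below nominal is ~0.90
        assert cover_theta / n_rep >= 0.90
        assert cover_beta / n_rep >= 0.90
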