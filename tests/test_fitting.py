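"""Likelihood construction, exclusion rules and the nested optimization."""

import numpy as np
import pytest

import poprime as pp
from poprime.fitting import valid_mask
from poprime.paradigm import SessionData, TrialOutcome, session_to_arrays
from poprime.synth import weighted_rate_color_spec

NO_UPDATE_PARAMS = {"theta": 1.0, "s0_base": 0.0, "mu_r": 5.0, "sigma_r": 1.0, "tau": 0.3}


class TestSessionNegloglik:
    def test_all_trials_excluded_gives_zero(self, small_design):
        sess = SessionData(
            "p", "1", [(s, TrialOutcome(None, None, None)) for s in small_design]
        )
        nll = pp.session_negloglik(sess, pp.no_update_spec("LATER"), dict(NO_UPDATE_PARAMS))
        assert nll == 0.0

    def test_removing_one_valid_trial_changes_exactly_its_term(self, no_update_session):
        spec = pp.no_update_spec("LATER")
        full = pp.session_negloglik(no_update_session, spec, dict(NO_UPDATE_PARAMS))
        arrays = session_to_arrays(no_update_session)
        valid = valid_mask(arrays, pp.FitConfig())
        i = int(np.nonzero(valid)[0][5])
        stim, out = no_update_session.trials[i]
        dropped = SessionData(
            "p", "1",
            no_update_session.trials[:i]
            + [(stim, TrialOutcome(None, None, None))]
            + no_update_session.trials[i + 1:],
        )
        reduced = pp.session_negloglik(dropped, spec, dict(NO_UPDATE_PARAMS))
        from poprime.ea import LATERParams, later_density

        term = -np.log(
            later_density(out.rt, LATERParams(1.0, 0.0, 5.0, 1.0, 0.3))
        )
        assert full - reduced == pytest.approx(term, abs=1e-10)

    def test_true_parameters_beat_perturbed_ones(self, no_update_session):
        """Near the ML point, perturbing parameters should not help."""
        spec = pp.no_update_spec("LATER")
        cfg = pp.FitConfig()
        inner, nll_true, _ = pp.fit_inner(no_update_session, spec, {"tau": 0.3}, cfg)
        rng = np.random.default_rng(0)
        wins = 0
        for _ in range(40):
            pert = {k: v * (1 + rng.choice([-0.2, 0.2])) for k, v in inner.items()}
            pert["tau"] = 0.3
            pert["rules"] = {}
            wins += pp.session_negloglik(no_update_session, spec, pert, cfg) >= nll_true
        assert wins >= 36

    def test_excluded_trials_still_advance_rule_states(self, later_color_sessions):
        """Censoring outcomes must not change the modulation sequence."""
        from poprime.fitting import _modulations

        spec = weighted_rate_color_spec("LATER")
        cfg = pp.FitConfig()
        sess = later_color_sessions[0]
        censored = SessionData(
            sess.participant, sess.session,
            [(s, TrialOutcome(None, None, None)) for s, _ in sess.trials],
        )
        rp = {"color": {"alpha": 0.8, "delta": 0.2}}
        for a, b in zip(
            _modulations(session_to_arrays(sess), spec, rp, cfg),
            _modulations(session_to_arrays(censored), spec, rp, cfg),
        ):
            np.testing.assert_array_equal(a, b)


class TestFitInner:
    def test_recovers_identifiable_functional(self, later_color_gen):
        """Without S0 updating, D/mu (the mean boundary-crossing time) is
        identifiable even though (theta, s0, mu) individually are not."""
        gen = later_color_gen
        design = pp.generate_design(pp.DesignConstraints(seed=30))
        sess = pp.simulate_session(
            design,
            pp.GenerativeSpec(model=pp.no_update_spec("LATER"), ea_params=gen.ea_params),
            seed=31,
        )
        inner, _, conv = pp.fit_inner(sess, pp.no_update_spec("LATER"), {"tau": 0.3})
        d_over_mu = (inner["theta"] - inner["s0_base"]) / inner["mu_r"]
        assert conv
        assert d_over_mu == pytest.approx(1.0 / 5.0, rel=0.05)

    def test_fit_is_at_least_as_good_as_truth(self, no_update_session):
        spec = pp.no_update_spec("LATER")
        _, nll_fit, _ = pp.fit_inner(no_update_session, spec, {"tau": 0.3})
        nll_true = pp.session_negloglik(no_update_session, spec, dict(NO_UPDATE_PARAMS))
        assert nll_fit <= nll_true + 1e-9

    def test_deterministic_given_seed(self, no_update_session):
        spec = pp.no_update_spec("LATER")
        cfg = pp.FitConfig(seed=5)
        a = pp.fit_inner(no_update_session, spec, {"tau": 0.3}, cfg)
        b = pp.fit_inner(no_update_session, spec, {"tau": 0.3}, cfg)
        assert a == b


class TestFitModel:
    def test_parameter_counting_contract(self):
        assert pp.no_update_spec("LATER").n_free_parameters == 5
        spec = weighted_rate_color_spec("LATER")  # alpha + delta
        assert spec.n_free_parameters == 7

    def test_aic_identity_and_convergence(self, no_update_session, fast_config):
        res = pp.fit_model(no_update_session, pp.no_update_spec("LATER"), fast_config)
        assert res.aic == pytest.approx(
            2 * res.n_free_parameters - 2 * res.loglik, abs=1e-10
        )
        assert res.n_valid_trials > 0
        assert res.converged

    def test_outer_search_improves_on_default_outer_point(self, no_update_session, fast_config):
        spec = pp.no_update_spec("LATER")
        res = pp.fit_model(no_update_session, spec, fast_config)
        _, nll_default, _ = pp.fit_inner(no_update_session, spec, {"tau": 0.3}, fast_config)
        assert -res.loglik <= nll_default + 1e-6

    def test_rejects_mismatched_rule_uv(self):
        from poprime.rules import get_rule_spec

        with pytest.raises(ValueError):
            pp.ModelSpec(
                "LATER",
                get_rule_spec("color", "weighted_rate"),  # color rule in rcf slot
                get_rule_spec("color", "no_update"),
                get_rule_spec("position", "no_update"),
            )
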