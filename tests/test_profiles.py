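"""Normalized RTs and n-back temporal profiles, data and model."""

import numpy as np
import pytest

import poprime as pp
from poprime.fitting import FitResult
from poprime.paradigm import SessionData
from poprime.profiles import model_predicted_profile, nback_profile, normalize_rts
from poprime.synth import GenerativeSpec, weighted_rate_color_spec
from poprime.ea import LATERParams


def truth_fit(gen: GenerativeSpec) -> FitResult:
    """Wrap the generating parameters as a FitResult (no refit needed for
    self-consistency checks)."""
    p = gen.ea_params
    inner = {"theta": p.theta, "s0_base": p.s0_base, "mu_r": p.mu_r, "sigma_r": p.sigma_r}
    k = gen.model.n_free_parameters
    return FitResult(
        model=gen.model, inner_params=inner, tau=p.tau, rule_params=gen.rule_params,
        loglik=np.nan, n_free_parameters=k, aic=np.nan, converged=True, n_valid_trials=0,
    )


@pytest.fixture(scope="module")
def color_study(later_color_gen):
    """Six simulated participants x 1 session from the color-rule truth."""
    return pp.simulate_study(later_color_gen, n_participants=6, n_sessions=1, seed=50)


class TestNormalizeRts:
    def test_output_mean_is_exactly_zero(self, no_update_session):
        vals = normalize_rts(no_update_session)
        assert vals.mean() == pytest.approx(0.0, abs=1e-12)

    def test_constant_rts_normalize_to_zero(self, small_design):
        trials = [
            (s, pp.TrialOutcome(s.notch, True, 0.5)) for s in small_design
        ]
        sess = SessionData("p", "1", trials)
        assert np.allclose(normalize_rts(sess), 0.0)

    def test_sessions_normalized_independently(self, later_color_sessions):
        a, b = (normalize_rts(s) for s in later_color_sessions)
        assert a.mean() == pytest.approx(0.0, abs=1e-12)
        assert b.mean() == pytest.approx(0.0, abs=1e-12)

    def test_no_valid_trials_raises(self, small_design):
        sess = SessionData(
            "p", "1", [(s, pp.TrialOutcome(None, None, None)) for s in small_design]
        )
        with pytest.raises(ValueError):
            normalize_rts(sess)


class TestNbackProfile:
    def test_lag1_color_repetition_benefit(self, color_study):
        prof = nback_profile(color_study, "color", max_lag=8)
        lag1 = prof[prof.lag == 1].set_index("condition")
        assert lag1.loc["repeat", "mean_nrt"] < lag1.loc["switch", "mean_nrt"]

    def test_effect_decays_with_lag(self, color_study):
        prof = nback_profile(color_study, "color", max_lag=8)
        wide = prof.pivot_table(index="lag", columns="condition", values="mean_nrt")
        eff = (wide["switch"] - wide["repeat"]).to_numpy()
        # alpha < 1 forgetting: late lags carry much less than lag 1
        assert eff[0] > 0
        assert np.mean(eff[4:]) < 0.5 * eff[0]

    def test_shuffling_trials_destroys_the_lag1_effect(self, color_study):
        rng = np.random.default_rng(3)
        shuffled = []
        for s in color_study:
            idx = rng.permutation(len(s))
            shuffled.append(SessionData(s.participant, s.session, [s.trials[i] for i in idx]))
        prof = nback_profile(shuffled, "color", max_lag=1)
        lag1 = prof[prof.lag == 1].set_index("condition")
        diff = lag1.loc["switch", "mean_nrt"] - lag1.loc["repeat", "mean_nrt"]
        ci = np.nanmax(lag1.ci_halfwidth.to_numpy())
        assert abs(diff) < max(ci, 0.01)

    def test_cell_counts_cover_all_classifiable_pairs(self, color_study):
        prof = nback_profile(color_study, "position", max_lag=4)
        n_valid = sum(len(normalize_rts(s)) for s in color_study)
        for lag in range(1, 5):
            cells = prof[prof.lag == lag]
            n_classifiable = sum(
                (normalize_rts(s).index >= lag).sum() for s in color_study
            )
            assert cells.n_trials.sum() == n_classifiable
            assert set(cells.condition) == {"TT", "TN", "TD"}

    def test_lag_longer_than_session_rejected(self, color_study):
        with pytest.raises(ValueError):
            nback_profile(color_study, "color", max_lag=10**4)


class TestModelPredictedProfile:
    def test_no_update_model_predicts_flat_profiles(self, no_update_session, later_color_gen):
        gen_flat = GenerativeSpec(
            model=pp.no_update_spec("LATER"), ea_params=later_color_gen.ea_params
        )
        prof = model_predicted_profile(
            no_update_session, truth_fit(gen_flat), "color", max_lag=4
        )
        assert prof.mean_nrt.std() == pytest.approx(0.0, abs=1e-10)

    def test_same_cells_and_counts_as_data_profile(self, color_study, later_color_gen):
        data = nback_profile(color_study, "color", max_lag=4)
        model = model_predicted_profile(
            color_study, truth_fit(later_color_gen), "color", max_lag=4
        )
        assert (data.source == "data").all() and (model.source == "model").all()
        for col in ("lag", "condition", "n_trials"):
            assert list(data[col]) == list(model[col])

    def test_model_tracks_data_within_confidence_intervals(self, color_study, later_color_gen):
        data = nback_profile(color_study, "color", max_lag=8)
        model = model_predicted_profile(
            color_study, truth_fit(later_color_gen), "color", max_lag=8
        )
        merged = data.merge(model, on=["lag", "condition"], suffixes=("_d", "_m"))
        inside = np.abs(merged.mean_nrt_d - merged.mean_nrt_m) <= merged.ci_halfwidth_d
        assert inside.mean() >= 0.85
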