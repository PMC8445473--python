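"""Updating-rule dynamics: registry, hand examples, conservation, limits."""

import numpy as np
import pytest

import poprime as pp
from poprime.paradigm import session_to_arrays
from poprime.rules import (
    Trial,
    belief_grid,
    beta_prior_on_grid,
    get_rule_spec,
    make_rule,
    registry_levels,
    run_rules,
)
from poprime.synth import generate_fixture_suite


def random_trials(n, rng, uv_levels=8):
    """Random valid position-uv trial stream (same-parity occupancy)."""
    out = []
    for _ in range(n):
        parity = int(rng.integers(2))
        occ = np.array([p for p in range(8) if p % 2 == parity])
        rng.shuffle(occ)
        out.append((int(occ[0]), occ[1:4].copy()))
    return out


def as_trial(tpos, dists, uv_value=None, rep=None):
    return Trial(
        uv_value=tpos if uv_value is None else uv_value,
        rep=rep,
        target_pos=tpos,
        distractors=np.asarray(dists),
    )


class TestRegistry:
    @pytest.mark.parametrize("uv,n", [("rcf", 12), ("color", 8), ("position", 10)])
    def test_level_counts(self, uv, n):
        assert len(registry_levels(uv)) == n

    def test_no_update_is_first_level(self):
        for uv in ("rcf", "color", "position"):
            assert registry_levels(uv)[0].name == "no_update"
            assert registry_levels(uv)[0].n_params == 0

    def test_parameter_counts_between_zero_and_three(self):
        for uv in ("rcf", "color", "position"):
            for spec in registry_levels(uv):
                assert 0 <= spec.n_params <= 3
                assert len(spec.param_bounds) == spec.n_params


class TestHandExamples:
    def test_weighted_rate_two_levels(self):
        eng = make_rule(get_rule_spec("color", "weighted_rate"), {"alpha": 1.0, "delta": 0.2})
        eng.step(as_trial(0, [2, 4, 6], uv_value=0))
        np.testing.assert_allclose(eng.w, [1.2, 0.8])
        assert eng.w.sum() == pytest.approx(2.0)

    def test_weighted_rate_distractor_inhibition(self):
        eng = make_rule(
            get_rule_spec("position", "weighted_rate_di"),
            {"alpha": 1.0, "delta_t": 0.7, "delta_d": 0.3},
        )
        eng.step(as_trial(0, [2, 4, 6]))
        assert eng.w[0] == pytest.approx(1.76)
        for d in (2, 4, 6):
            assert eng.w[d] == pytest.approx(0.8)
        for e in (1, 3, 5, 7):
            assert eng.w[e] == pytest.approx(0.96)
        assert eng.w.sum() == pytest.approx(8.0)

    def test_matched_ndt_inhibition(self):
        eng = make_rule(
            get_rule_spec("position", "weighted_ndt_matched"), {"alpha": 1.0, "delta": 0.03}
        )
        eng.step(as_trial(0, [2, 4, 6]))
        assert eng.dtau[0] == pytest.approx(-0.03)
        for d in (2, 4, 6):
            assert eng.dtau[d] == pytest.approx(0.01)
        assert eng.dtau.sum() == pytest.approx(0.0, abs=1e-15)

    def test_step_rate_zero_delta_is_inert(self):
        eng = make_rule(get_rule_spec("color", "step_rate"), {"alpha": 0.9, "delta": 0.0})
        for rep in (None, True, False, False, True):
            _, scale, _ = eng.step(as_trial(0, [2, 4, 6], uv_value=0, rep=rep))
            assert scale == 1.0

    def test_beta_bernoulli_log_two(self):
        eng = make_rule(get_rule_spec("rcf", "pi_bayes_s0"), {"alpha": 1.0, "beta0": 1.0})
        ds0, _, _ = eng.step(as_trial(0, [2, 4, 6], uv_value=0))
        assert ds0 == pytest.approx(0.0, abs=1e-12)  # symmetric start
        ds0, _, _ = eng.step(as_trial(0, [2, 4, 6], uv_value=0))
        assert ds0 == pytest.approx(np.log(2.0), abs=1e-4)
        # antisymmetry: querying the other state negates the log odds
        eng2 = make_rule(get_rule_spec("rcf", "pi_bayes_s0"), {"alpha": 1.0, "beta0": 1.0})
        eng2.step(as_trial(0, [2, 4, 6], uv_value=0))
        ds0b, _, _ = eng2.step(as_trial(0, [2, 4, 6], uv_value=1))
        assert ds0b == pytest.approx(-ds0, abs=1e-12)

    def test_dbm_alpha_zero_freezes_the_prior(self):
        eng = make_rule(get_rule_spec("rcf", "pi_bayes_s0"), {"alpha": 0.0, "beta0": 2.0})
        rng = np.random.default_rng(1)
        for _ in range(30):
            ds0, _, _ = eng.step(as_trial(0, [2, 4, 6], uv_value=int(rng.integers(2))))
            assert ds0 == pytest.approx(0.0, abs=1e-12)

    def test_binary_rate_bounds_checked(self):
        with pytest.raises(ValueError):
            make_rule(get_rule_spec("color", "binary_rate"), {"kappa": 1.4})

    def test_pg_omega_bound_checked(self):
        with pytest.raises(ValueError):
            make_rule(
                get_rule_spec("rcf", "pg_bayes_s0"), {"alpha": 0.9, "omega": 1.0, "beta0": 1.0}
            )


class TestConservation:
    """Weight sums are invariants of every weighted rule's dynamics."""

    N_UPDATES = 10000

    @pytest.mark.parametrize(
        "uv,name,params,total",
        [
            ("color", "weighted_rate", {"alpha": 0.85, "delta": 0.23}, 2.0),
            ("rcf", "weighted_rate", {"alpha": 0.6, "delta": 0.4}, 2.0),
            ("position", "weighted_rate", {"alpha": 0.92, "delta": 0.31}, 8.0),
            (
                "position",
                "weighted_rate_di",
                {"alpha": 0.88, "delta_t": 0.5, "delta_d": 0.2},
                8.0,
            ),
            ("position", "weighted_rate_matched", {"alpha": 0.7, "delta": 0.3}, 8.0),
        ],
    )
    def test_rate_weights_sum_to_n(self, uv, name, params, total):
        rng = np.random.default_rng(42)
        eng = make_rule(get_rule_spec(uv, name), params)
        for tpos, dists in random_trials(self.N_UPDATES, rng):
            uv_value = tpos if uv == "position" else int(rng.integers(2))
            eng.step(as_trial(tpos, dists, uv_value=uv_value))
        assert eng.w.sum() == pytest.approx(total, abs=1e-9)

    @pytest.mark.parametrize(
        "uv,name,params",
        [
            ("color", "weighted_ndt", {"alpha": 0.8, "delta": 0.05}),
            ("position", "weighted_ndt", {"alpha": 0.95, "delta": 0.04}),
            ("position", "weighted_ndt_di", {"alpha": 0.9, "delta_t": 0.06, "delta_d": 0.02}),
            ("position", "weighted_ndt_matched", {"alpha": 0.75, "delta": 0.05}),
        ],
    )
    def test_ndt_offsets_sum_to_zero(self, uv, name, params):
        rng = np.random.default_rng(43)
        eng = make_rule(get_rule_spec(uv, name), params)
        for tpos, dists in random_trials(self.N_UPDATES, rng):
            uv_value = tpos if uv == "position" else int(rng.integers(2))
            eng.step(as_trial(tpos, dists, uv_value=uv_value))
        assert eng.dtau.sum() == pytest.approx(0.0, abs=1e-12)

    def test_per_position_sums_for_position_specific_rates(self):
        rng = np.random.default_rng(44)
        for name in ("pd_weighted_rate", "pg_weighted_rate"):
            params = {"alpha": 0.85, "delta": 0.2}
            if name == "pg_weighted_rate":
                params["omega"] = 0.6
            eng = make_rule(get_rule_spec("color", name), params)
            for tpos, dists in random_trials(2000, rng):
                eng.step(as_trial(tpos, dists, uv_value=int(rng.integers(2))))
            np.testing.assert_allclose(eng.w.sum(axis=0), 2.0, atol=1e-9)


class TestLimitEquivalences:
    def _drive(self, eng, seq):
        return [eng.step(tr)[0] for tr in seq]

    def _seq(self, n=40, seed=5):
        rng = np.random.default_rng(seed)
        return [
            as_trial(tpos, dists, uv_value=int(rng.integers(2)))
            for tpos, dists in random_trials(n, rng)
        ]

    def test_pg_reduces_to_pd_as_omega_vanishes(self):
        seq = self._seq()
        pd = make_rule(get_rule_spec("rcf", "pd_bayes_s0"), {"alpha": 0.9, "beta0": 1.5})
        pg = make_rule(
            get_rule_spec("rcf", "pg_bayes_s0"),
            {"alpha": 0.9, "omega": 1e-9, "beta0": 1.5},
            _validate=False,
        )
        np.testing.assert_allclose(self._drive(pd, seq), self._drive(pg, seq), atol=1e-6)

    def test_pg_reduces_to_pi_as_omega_approaches_one(self):
        seq = self._seq()
        pi = make_rule(get_rule_spec("rcf", "pi_bayes_s0"), {"alpha": 0.9, "beta0": 1.5})
        pg = make_rule(
            get_rule_spec("rcf", "pg_bayes_s0"),
            {"alpha": 0.9, "omega": 1.0 - 1e-12, "beta0": 1.5},
            _validate=False,
        )
        np.testing.assert_allclose(self._drive(pi, seq), self._drive(pg, seq), atol=1e-6)

    def test_ps_reduces_to_pd_as_sigma_vanishes(self):
        seq = self._seq()
        pd = make_rule(get_rule_spec("rcf", "pd_bayes_s0"), {"alpha": 0.9, "beta0": 1.5})
        ps = make_rule(
            get_rule_spec("rcf", "ps_bayes_s0"),
            {"alpha": 0.9, "sigma_spread": 0.05, "beta0": 1.5},
            _validate=False,
        )
        np.testing.assert_allclose(self._drive(pd, seq), self._drive(ps, seq), atol=1e-6)

    def test_pg_step_ndt_collapses_to_pd_step_ndt(self):
        seq = self._seq()
        p15 = make_rule(get_rule_spec("rcf", "pd_step_ndt"), {"alpha": 0.9, "delta": 0.05})
        p16 = make_rule(
            get_rule_spec("rcf", "pg_step_ndt"),
            {"alpha": 0.9, "omega": 1e-12, "delta": 0.05},
            _validate=False,
        )
        a = [eng[2] for eng in (p15.step(tr) for tr in seq)]
        b = [eng[2] for eng in (p16.step(tr) for tr in seq)]
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestGridAgainstConjugateOracle:
    def test_posterior_predictive_matches_beta_bernoulli(self):
        """With no forgetting the grid belief must track the conjugate form."""
        rng = np.random.default_rng(6)
        for _ in range(50):
            beta0 = float(rng.uniform(0.5, 5.0))
            obs = rng.integers(2, size=rng.integers(1, 25))
            eng = make_rule(
                get_rule_spec("rcf", "pi_bayes_s0"), {"alpha": 1.0, "beta0": beta0}
            )
            for o in obs:
                eng.step(as_trial(0, [2, 4, 6], uv_value=int(o)))
            heads = int(np.sum(obs == 0))
            pred_exact = (beta0 + heads) / (2.0 * beta0 + len(obs))
            pred_grid = float(np.sum(eng.belief * eng.grid))
            assert pred_grid == pytest.approx(pred_exact, abs=1e-4)


class TestSymmetryAndOrder:
    def test_relabeling_binary_uv_mirrors_the_learned_state(self):
        """Swapping the two UV labels swaps weight vectors and negates the
        fixed-boundary log odds, leaving the occurring-state head start
        unchanged (the model cannot prefer a label per se)."""
        from poprime.rules import s0_from_belief

        seq = np.random.default_rng(8).integers(2, size=60)

        a = make_rule(get_rule_spec("rcf", "pi_bayes_s0"), {"alpha": 0.9, "beta0": 1.0})
        b = make_rule(get_rule_spec("rcf", "pi_bayes_s0"), {"alpha": 0.9, "beta0": 1.0})
        wa = make_rule(get_rule_spec("color", "weighted_rate"), {"alpha": 0.8, "delta": 0.2})
        wb = make_rule(get_rule_spec("color", "weighted_rate"), {"alpha": 0.8, "delta": 0.2})
        for i, v in enumerate(seq):
            rep = None if i == 0 else bool(seq[i] == seq[i - 1])
            ds0_a = a.step(as_trial(0, [2, 4, 6], uv_value=int(v), rep=rep))[0]
            ds0_b = b.step(as_trial(0, [2, 4, 6], uv_value=int(1 - v), rep=rep))[0]
            assert ds0_a == pytest.approx(ds0_b, abs=1e-12)  # occurring-state invariance
            # fixed-state log odds negate: P_b(state 0) = 1 - P_a(state 0)
            lo_a = s0_from_belief(a.belief, a.grid, True)
            lo_b = s0_from_belief(b.belief, b.grid, True)
            assert lo_a == pytest.approx(-lo_b, abs=1e-10)
            wa.step(as_trial(0, [2, 4, 6], uv_value=int(v), rep=rep))
            wb.step(as_trial(0, [2, 4, 6], uv_value=int(1 - v), rep=rep))
        np.testing.assert_allclose(wa.w, wb.w[::-1], atol=1e-12)

    def test_forgetting_makes_order_matter(self):
        rng = np.random.default_rng(9)
        seq = list(rng.integers(2, size=40))
        perm = list(np.array(seq)[rng.permutation(40)])
        assert seq != perm

        def final_weights(values):
            eng = make_rule(get_rule_spec("color", "weighted_rate"), {"alpha": 0.8, "delta": 0.2})
            for v in values:
                eng.step(as_trial(0, [2, 4, 6], uv_value=int(v)))
            return eng.w.copy()

        assert not np.allclose(final_weights(seq), final_weights(perm))


class TestFixtureNarratives:
    """The 8-trial fixtures reproduce the documented weight trajectories."""

    def _weight_series(self, session, uv, name, params):
        arrays = session_to_arrays(session)
        spec = get_rule_spec(uv, name)
        _, scale, _ = run_rules(arrays, [(spec, params)])
        return scale  # rate scale on trial n = weight of the trial's UV value

    def test_color_fixture_weight_trajectory(self):
        fx = generate_fixture_suite(seed=0)["color"]
        w = self._weight_series(fx, "color", "weighted_rate", {"alpha": 0.8, "delta": 0.2})
        # second repetition in a row accumulates: trial 3 > trial 2 (> 1)
        assert w[2] > w[1] > 1.0
        # repetition after a run of the other color is much weaker
        assert w[4] < w[2]
        # switch trials carry weight below baseline
        assert w[3] < 1.0 and w[5] < 1.0

    def test_position_fixture_distractor_inhibition(self):
        fx = generate_fixture_suite(seed=0)["position"]
        w = self._weight_series(
            fx, "position", "weighted_rate_di", {"alpha": 0.9, "delta_t": 0.3, "delta_d": 0.2}
        )
        # both TD transitions dip below baseline; the second is lower because
        # distractors kept occupying that position in the interim
        assert w[3] < 1.0 and w[6] < 1.0
        assert w[6] < w[3]

    def test_rcf_fixture_has_position_repeat_with_notch_switch(self):
        fx = generate_fixture_suite(seed=0)["rcf"]
        s1, s2 = fx.stimuli[0], fx.stimuli[1]
        assert s1.target_position == s2.target_position
        assert s1.notch != s2.notch
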