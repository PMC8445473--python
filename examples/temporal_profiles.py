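"""n-back temporal profiles: data vs model, as in the profile figures.

Eight participants are simulated from the winning rule combination
(position-gradient Bayesian starting point for the response feature,
weighted rate for color, weighted rate with distractor inhibition for
position). Normalized RTs (RT minus the session mean) are averaged per
lag and inter-trial condition; the model rows replace each trial's RT
with the modulated model's expected RT over the 0.2-1.5 s window.
"""

from dataclasses import replace

import poprime as pp
from poprime.ea import LATERParams
from poprime.fitting import FitResult
from poprime.profiles import model_predicted_profile, nback_profile
from poprime.rules import get_rule_spec
from poprime.synth import GenerativeSpec

spec = replace(
    pp.no_update_spec("LATER"),
    rcf_rule=get_rule_spec("rcf", "pg_bayes_s0"),
    color_rule=get_rule_spec("color", "weighted_rate"),
    position_rule=get_rule_spec("position", "weighted_rate_di"),
)
rule_params = {
    "rcf": {"alpha": 0.9, "omega": 0.5, "beta0": 2.0},
    "color": {"alpha": 0.8, "delta": 0.2},
    "position": {"alpha": 0.9, "delta_t": 0.3, "delta_d": 0.2},
}
p = LATERParams(theta=1.0, s0_base=-0.3, mu_r=5.0, sigma_r=1.0, tau=0.3)
gen = GenerativeSpec(model=spec, ea_params=p, rule_params=rule_params,
                     lapse_probability=0.02)
study = pp.simulate_study(gen, n_participants=8, n_sessions=1, seed=60)

fit = FitResult(  # evaluate at the generating parameters (self-consistency)
    model=spec,
    inner_params={"theta": p.theta, "s0_base": p.s0_base, "mu_r": p.mu_r,
                  "sigma_r": p.sigma_r},
    tau=p.tau, rule_params=rule_params, loglik=float("nan"),
    n_free_parameters=spec.n_free_parameters, aic=float("nan"),
    converged=True, n_valid_trials=0,
)

data = nback_profile(study, "position", max_lag=8)
model = model_predicted_profile(study, fit, "position", max_lag=8)
wide_d = data.pivot_table(index="lag", columns="condition", values="mean_nrt")
wide_m = model.pivot_table(index="lag", columns="condition", values="mean_nrt")
print("data, mean normalized RT (s) by lag:")
print(wide_d.round(3).to_string())
print("\nmodel prediction:")
print(wide_m.round(3).to_string())
# at lag 1: TT < TN < TD (facilitation at the previous target position,
# a cost at previous distractor positions), decaying over lags; the model
# rows track the data because both share the same generative history.
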