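"""The behavioral signature of generalization, and its absence.

After an incorrect free choice, do intervening rewarded forced-choice
trials make the next free choice more accurate?  For an agent that shares
states between trial types (four-state) they must — the forced outcomes
update the very values that guide free choices.  For a six-state agent
they carry no information about free-choice values, so the regression
slope is zero.
"""

from odorchoice import (
    ModelParams,
    extract_generalization_cases,
    fit_generalization_regression,
    simulate_dataset,
)

population = {
    f"rat{i}": ModelParams(eta=0.3, gamma=0.8, beta=3.0, persev_p=0.2, lapse=0.02)
    for i in range(6)
}
for model in ("six_state", "four_state"):
    data = simulate_dataset(model, population, n_sessions=8, seed=11)
    cases = extract_generalization_cases(data)
    result = fit_generalization_regression(cases, n_steps=1000, n_warmup=650, seed=2)
    lo, hi = result.group_theta_hdi
    verdict = "covers 0 — no generalization" if lo < 0 < hi else "excludes 0"
    print(f"{model}: {len(cases)} cases, group slope {result.group_theta_mean:+.3f}, "
          f"95% HDI [{lo:+.3f}, {hi:+.3f}] ({verdict})")
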