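"""Simulate a full study and run the complete statistical analysis chain.

Simulates the 8-fish design (3 vs 6 training, probe tests) with the
paper-like preset, then: (1) backward-eliminates a binomial GLMM of the
test choices on the control factors and the comparison, (2) summarises the
pooled choices with an exact binomial test and Cohen's g, and (3) runs the
congruency-level analysis with Tukey-adjusted contrasts.
"""

from numfish import backward_select, congruency_analysis, exact_binomial, inv_logit
from numfish.synthdata import simulate_study

table = simulate_study("exp1", seed=1)
tests = table[(table["phase"] == "test") & (table["responded"] == 1)]

fit, trace = backward_select(
    tests, ["geometry_control", "spatial_control", "comparison"], criterion="BIC"
)
print(f"selected fixed terms: {trace[-1]['terms'] or 'intercept only'}")
print(
    f"GLMM intercept: {fit.fixed_effects[0]:.3f} +/- {fit.fixed_se[0]:.3f} "
    f"log-odds = {inv_logit(fit.fixed_effects[0]):.3f} natural units; "
    f"random-intercept variance {fit.random_intercept_variance:.2e}"
)

s = exact_binomial(int(tests["chose_target"].sum()), len(tests))
print(
    f"pooled binomial: {s.k}/{s.n} = {s.p_hat:.3f} "
    f"(95% CI {s.ci_low:.3f}-{s.ci_high:.3f}), p = {s.p_value:.2e}, "
    f"Cohen's g = {s.cohens_g:.2f} ({s.g_band})"
)

cong = congruency_analysis(tests)
print("\ncongruency-level contrasts (Tukey-adjusted):")
print(cong["contrasts"][["contrast", "estimate", "p_adjusted"]].round(3).to_string(index=False))
print(
    "\nWith accuracy independent of the controls (the generating truth), no "
    "factor survives\nselection and all congruency contrasts are "
    "non-significant."
)
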