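"""Administer one adaptive (CAT) session to a simulated respondent.

A person with true measure theta = +0.5 answers items drawn from the
model; the engine picks each next item by maximal information and stops
under the compound rule (>= 7 items, reliability >= 0.90, settled
provisional measure). Prints the step-by-step trajectory and the
person-fit summary.
"""

from adlcat import fixture_bank, person_fit, run_cat

bank = fixture_bank("ADL-female")
session = run_cat(bank, method="MAP", true_theta=0.5, seed=42)

print(session.log_frame().to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(
    f"\nstopped: {session.stop_reason.value} after {session.n_administered} "
    f"of {len(bank)} items"
)
print(
    f"final: theta = {session.final.theta:+.3f}  SEM = {session.final.sem:.3f} "
    f"(true theta was +0.50; T score = {50 + 10 * session.final.theta:.1f})"
)

answers = [(bank.item(i), x) for i, x in zip(session.administered, session.responses)]
fit = person_fit(answers, session.final.theta)
print(
    f"person fit: outfit MNSQ = {fit.outfit_mnsq:.2f}, infit MNSQ = "
    f"{fit.infit_mnsq:.2f}, flagged responses (|z| >= 2): {list(fit.flagged) or 'none'}"
)
print(
    "\nMNSQ near 1 means the answers are as noisy as the model expects; "
    "values >= 2 would signal careless or aberrant responding."
)
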