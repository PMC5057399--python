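"""Score one fixed response pattern with the three person estimators.

Builds a short answer pattern on the male ADL bank and prints the
measure (theta, in logits), its standard error, and the implied person
reliability for MLE, MAP, and EAP.
"""

from adlcat import estimate, fixture_bank

bank = fixture_bank("ADL-male")

# (item, category): 0 is the lowest-functioning category of each item
pattern = [
    (bank.item("1. Washing face"), 1),
    (bank.item("26. Bladder management"), 2),
    (bank.item("32. Putting on clothes"), 2),
    (bank.item("12. Using a telephone"), 0),
    (bank.item("6. Preparing light meals"), 1),
]

for method in ("MLE", "MAP", "EAP"):
    est = estimate(pattern, method)
    print(
        f"{method}: theta = {est.theta:+.3f}  SEM = {est.sem:.3f}  "
        f"reliability = {est.reliability:.3f}  (n = {est.n_items} items)"
    )

print(
    "\ntheta is the person's ADL function on the logit scale (population "
    "~ N(0,1)); the Bayesian estimators (MAP, EAP) shrink toward 0 and "
    "carry smaller standard errors on short patterns."
)
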