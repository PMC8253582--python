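"""Estimate a 50% mechanical withdrawal threshold from an up-down staircase.

Simulates an animal whose true threshold is 0.5 g responding through a
logistic psychometric function, runs the adaptive staircase, and applies
the Dixon up-down estimator to the terminal response pattern.
"""

from qorscore import estimate_threshold, simulate_vonfrey_responses

session = simulate_vonfrey_responses(true_threshold_g=0.5, slope=10.0, seed=4)
print("staircase (X = withdrawal response, O = none):")
for t in session.trials:
    print(f"  {t.force_g:5.2f} g  {'X' if t.response else 'O'}")

est = estimate_threshold(session)
print(f"\nestimated 50% threshold: {est.threshold_g:.3f} g "
      f"(true 0.5 g, censored={est.censored})")
# The estimate lands within about half a filament step of the true
# threshold; values pinned at 0.04 or 15 g would be flagged censored.
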