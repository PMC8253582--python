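"""Score a single animal-day by hand: %MPE per domain, bins, composite.

Uses the reported laparotomy day-1 group medians as the "measurements" and
the naive medians as the baseline profile, so the printed composite shows
how a freshly operated animal scores.
"""

from qorscore import DeficitAnchors, daily_composite, domain_score, percent_mpe

baselines = {  # healthy pre-operative profile
    "food_g": 17.25,        # g/day
    "sucrose_pref_pct": 92, # %
    "distance_m": 240,      # m/night
    "vonfrey_g": 1.2,       # g
    "transit_min": 72.5,    # min
    "social_s": 50,         # s
}
day1 = {  # post-operative day 1
    "food_g": 6.75,
    "sucrose_pref_pct": 88,
    "distance_m": 139,
    "vonfrey_g": 0.28,
    "transit_min": 617,
    "social_s": 41,
}

anchors = DeficitAnchors()
scores = {}
print(f"{'domain':18}{'test':>8}{'base':>8}{'anchor':>8}{'%MPE':>8}{'score':>6}")
for d, test in day1.items():
    mpe = percent_mpe(test, baselines[d], anchors.for_domain(d), d)
    scores[d] = domain_score(mpe)
    print(f"{d:18}{test:8.2f}{baselines[d]:8.2f}"
          f"{anchors.for_domain(d):8.2f}{mpe.mpe_pct:8.1f}{scores[d]:6d}")

composite = daily_composite("rat_01", 1, scores)
print(f"\ndaily composite: {composite.total}/18 "
      "(18 = little to no impairment, 0 = gross impairment)")
# A freshly laparotomized animal loses most of its score to the large
# food, transit, von Frey and distance deficits.
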