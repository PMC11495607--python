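"""Small-sample comparisons: permutation tests and the c-value budget.

A 21-person convenience sample (research-personnel scale) rates four
factors; all pairwise PSup comparisons get 1000-permutation randomization
tests, and comparisons are selected in ascending c-value order under the
cumulative 5% budget.  Finally a posterior population distribution is
compared against the fixed small sample with psup_pop_vs_fixed.
"""

import itertools

import numpy as np

import mrpsup as m

rng = np.random.default_rng(21)
n = 21
items = {
    "risk_to_participants": 8.6,    # latent means on a 10-point scale
    "risk_comprehension": 8.2,
    "openness": 6.8,
    "payment_for_risk": 5.2,
}
cuts = np.linspace(-2.2, 2.2, 9) + 1.2
ratings = {
    name: np.clip(
        1 + np.searchsorted(cuts, (mu - 6.0) / 2.0 + rng.standard_normal(n)),
        1, 10,
    )
    for name, mu in items.items()
}

tests = []
for i, (a, b) in enumerate(itertools.combinations(items, 2)):
    tests.append(
        m.randomization_test(ratings[a], ratings[b], permutations=1000,
                             seed=100 + i, label=f"{a} > {b}")
    )
selected = m.select_within_budget(tests, budget=0.05)

print(f"{'comparison':45s} {'PSup':>6s} {'c':>7s} selected")
for t in sorted(tests, key=lambda t: t.c_value):
    print(f"{t.label:45s} {t.observed:6.3f} {t.c_value:7.3f} {t.selected}")
print()
print("Comparisons are admitted in ascending c-value order while the running")
print("sum of admitted c-values stays at or below 0.05, bounding expected")
print("false positives per comparison set at 5%.")

# population posterior (here a Dirichlet stand-in over 10 categories) vs the
# fixed personnel ratings for one item
pop_probs = np.random.default_rng(5).dirichlet(np.arange(1, 11), size=2000)
res = m.psup_pop_vs_fixed(pop_probs, ratings["openness"],
                          pair=("population", "personnel"))
print()
print(f"PSup(population > personnel) for openness: {res.value:.3f} "
      f"[{res.hdi[0]:.3f}, {res.hdi[1]:.3f}]")
print("The personnel side is treated as fixed: only the population posterior")
print("contributes uncertainty.")
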