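"""Plan a diagnostic-accuracy validation study with Buderer's formula.

n = z^2 A(1-A) / (d^2 p): enough children that the disease-positive
subgroup supports estimating a 90% sensitivity to within +/-7% at 95%
confidence when a quarter of the population is affected.  Survey
adjustments (design effect, finite population, non-response) compose on
top.
"""

from cdst import adjust_n, buderer_n

base = buderer_n(expected_accuracy=0.90, d=0.07, p=0.25, conf_level=0.95)
print(f"base requirement: {base} children")

inflated = adjust_n(base, deff=1.2)
print(f"with design effect 1.2: {inflated}")

finite = adjust_n(base, deff=1.2, population_size=5000)
print(f"plus finite-population correction (N=5000): {finite}")

with_nr = adjust_n(base, deff=1.2, nonresponse_rate=0.1, population_size=5000)
print(f"plus 10% non-response: {with_nr}")
# 283 is the bare Buderer requirement; each survey adjustment then scales
# it (clustering inflates, a finite source population shrinks, expected
# non-response inflates again).
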