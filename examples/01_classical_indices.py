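"""Classical lifespan-inequality indices on small worked distributions.

Builds two tiny age-at-death distributions by hand and prints the absolute
Gini (AID), relative Gini, standard deviation and CV for each.
"""

import lifeineq as li

fx = li.fixtures()

uniform = fx["uniform"](10)  # equal point masses on ages 0..9
print("uniform point masses on ages 0..9:")
print(f"  e0    = {uniform.e0:.2f} years  (mean age at death)")
print(f"  AID   = {li.aid(uniform):.4f} years  (half the mean |age_i - age_j| gap)")
print(f"  G     = {li.gini(uniform):.4f}        (AID / e0, in [0,1])")
print(f"  sigma = {li.std_dev(uniform):.4f} years, CV = {li.cv(uniform):.4f}")

toy = fx["worked_toy"]  # d = (0.1, 0.1, 0.8) at mean ages (0.3, 1.5, 7.0)
print("\nthree-interval toy table, d = (0.1, 0.1, 0.8):")
print(f"  e0  = {toy.e0:.2f} years")
print(f"  AID = {li.aid(toy):.4f} years, G = {li.gini(toy):.4f}")
print("\nA higher AID/G means two randomly drawn individuals die at more")
print("different ages - more lifespan inequality.")
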