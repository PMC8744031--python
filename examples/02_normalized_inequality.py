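"""Normalized inequality: comparing against the most unequal distribution possible.

Constructs the two-point maximal-inequality benchmark M(e0, omega) for a
modern low-mortality population and shows how the normalized Gini G*
reinterprets its classical Gini.
"""

import lifeineq as li

OMEGA = 122.0  # oldest recorded age at death

lt = li.siler_lifetable(li.SILER_LOW_MORTALITY)
dist = li.deaths_distribution(lt)
e0 = dist.e0
g = li.gini(dist)

bench = li.max_inequality_distribution(e0, OMEGA)
print(f"low-mortality life table: e0 = {e0:.2f} years, classical G = {g:.4f}")
print(f"benchmark M(e0, {OMEGA:.0f}): share {bench.s1:.3f} dies at age 0, "
      f"share {1 - bench.s1:.3f} at age {OMEGA:.0f}")
print(f"maximal Gini at this e0 = {li.max_index_value('G', e0, OMEGA):.4f}")
print(f"normalized Gini G*      = {li.normalized_gini(dist, OMEGA):.4f}")
print(f"normalized AID (same by construction) = {li.normalized_aid(dist, OMEGA):.4f}")
print()
print("G* says how close the population sits to the most unequal mortality")
print("regime compatible with its own longevity: the classical G looks low")
print("partly because a high e0 leaves little room for variability.")
print()
for omega in (122.0, 150.0, 200.0, 1000.0, 1e6):
    print(f"  omega = {omega:>9.0f}:  G* = {li.normalized_gini(dist, omega):.4f}")
print(f"  (G* falls toward the classical G = {g:.4f} as omega grows)")
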