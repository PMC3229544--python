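"""The exact Mann-Whitney rank test at the study's group sizes.

With 3-5 arrays per group the normal approximation is useless, so both
tail probabilities are computed by enumerating every group assignment of
the pooled mid-ranked values: C(8,3) = 56 assignments for a 5-vs-3
comparison.
"""

import probedex as px

# complete separation, 5 experimental vs 3 control arrays
x = [0.4, 0.5, 0.6, 0.7, 0.8]
y = [0.1, 0.2, 0.3]
p_upper, p_lower = px.mw_exact(x, y)
print(f"complete separation 5v3: p_upper={p_upper:.5f} (=1/56), p_lower={p_lower:.3f}")
print(f"letter: {px.assign_letter(p_upper, p_lower)}")
# p_upper = 1/56 is the smallest tail a 5v3 comparison can produce; it
# clears the 0.05 cut, so the probe is marked 'H' for this comparison.

# interleaved groups: no evidence either way
x = [2.0, 4.0, 6.0, 7.0, 8.0]
y = [1.0, 3.0, 5.0]
p_upper, p_lower = px.mw_exact(x, y)
print(f"interleaved 5v3: p_upper={p_upper:.4f} (=7/56), letter={px.assign_letter(p_upper, p_lower)}")

# ties are handled by mid-ranking before enumeration
p_upper, p_lower = px.mw_exact([1.0, 1.0, 2.0], [1.0, 2.0, 2.0])
print(f"heavily tied 3v3: p_upper={p_upper:.3f}, p_lower={p_lower:.3f}")
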