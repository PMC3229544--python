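"""Attributing an expression profile to a transcript.

A transcript carrying 9 probes, 7 of which share the same down-regulated
expression string, is extremely unlikely to do so by chance: the
hypergeometric upper tail quantifies exactly that.
"""

from math import comb

import probedex as px

# 7 of the transcript's 9 probes fall in a profile cluster of size 7,
# among 100 retained probes in total
p = px.hypergeom_tail(7, 7, 9, 100)
print(f"pAX for 7/9 probes in a 7-probe cluster (T=100): {p:.3g}")
print(f"  closed form C(9,7)/C(100,7) = {comb(9, 7) / comb(100, 7):.3g}")

# the same count observed in a large unspecific cluster is unremarkable
print(f"pAX if the cluster had 60 probes instead:        {px.hypergeom_tail(7, 60, 9, 100):.3g}")

# BH adjustment over the full transcripts-x-profiles family
raw = [px.hypergeom_tail(7, 7, 9, 100), 0.004, 0.04]
adjusted = px.bh_adjust(raw, m_total=50)
for r, a in zip(raw, adjusted):
    print(f"p_raw={r:.3g} -> p_adj={a:.3g}")
# Only attributions with adjusted p < 0.05 declare the transcript
# differentially expressed with that profile.
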