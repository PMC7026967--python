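"""Alpha-diversity estimators and rarefaction on a toy community.

Builds one uneven community, rarefies it to a common depth and prints
the richness/evenness estimators with a line on how to read each.
"""

import numpy as np

from otupipe.diversity import ace, chao1, goods_coverage, rarefy, shannon, simpson

rng = np.random.default_rng(0)
# 40 OTUs with a log-series-like tail: a few dominants, many singletons
counts = np.sort(rng.geometric(0.05, 40))[::-1]
counts[-12:] = 1

print("community:", counts.tolist())
print(f"observed OTUs: {(counts > 0).sum()}")
print(f"Chao1: {chao1(counts):.1f}   (observed + F1(F1-1)/(2(F2+1)); >= observed)")
print(f"ACE: {ace(counts):.1f}     (coverage-based; uses classes with <= 10 reads)")
print(f"Shannon: {shannon(counts):.3f} (natural log; ln S = {np.log(len(counts)):.3f} if perfectly even)")
print(f"Simpson dominance: {simpson(counts):.3f} (probability two reads share an OTU; lower = more even)")
print(f"Good's coverage: {goods_coverage(counts):.1f}% (1 - singletons/reads)")

depth = 100
sub = rarefy(counts, depth, seed=42)
print(f"\nafter rarefying to {depth} reads: sum={sub.sum()}, observed={(sub > 0).sum()}")
# rarefaction removes depth bias before comparing samples; it never
# increases observed richness and is a single recorded-seed draw.
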