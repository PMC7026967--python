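"""Friedman test with Nemenyi post hoc and compact-letter display.

Four diet/phase groups, ten replicate samples each: one taxon is
programmed high in the first group, so the Friedman test rejects and
the Nemenyi letters isolate that group.
"""

import numpy as np

from otupipe.stats import friedman_test, nemenyi_posthoc

rng = np.random.default_rng(3)
groups = ["CON II", "PEP II", "CON III", "PEP III"]
# relative abundance (%) of one taxon across 10 replicates per group
values = np.column_stack(
    [
        rng.normal(30, 8, 10),  # high in CON II
        rng.normal(15, 8, 10),
        rng.normal(5, 3, 10),
        rng.normal(6, 3, 10),
    ]
).clip(min=0.0)

fr = friedman_test(values)
print(f"Friedman chi2 = {fr.statistic:.2f}, df = {fr.df}, p = {fr.p_value:.4g}")

nem = nemenyi_posthoc(values, groups, alpha=0.05)
print("\npairwise Nemenyi p-values:")
print(nem.p_matrix.round(4))
print("\ncompact letters:", nem.letters)
# groups sharing no letter differ at alpha = 0.05: the high group gets
# its own letter, mirroring the superscript notation of abundance tables.
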