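"""Gene-list enrichment and qPCR fold-change confirmation.

The summed-density enrichment test asks whether a DE gene set overlaps a
published target list more than chance; the ddCt helper converts qPCR
cycle thresholds into relative fold changes for wet-lab confirmation.
"""

import probedex as px

de_genes = {"Hif1a", "Vegfa", "Slc2a1", "Pgk1", "Mt2", "Ier3"}
target_lists = {
    "hif1_targets": {"Hif1a", "Vegfa", "Slc2a1", "Pgk1", "Ldha", "Eno1"},
    "unrelated": {"Actb", "Gapdh", "Tubb5"},
}
table = px.cross_validate(de_genes, target_lists, universe_size=20000)
print(table.to_string(index=False))
# QT is the observed overlap; p sums the hypergeometric densities from QT
# up to min(Q, T) — the chance of an overlap at least this large when Q
# genes are drawn from the universe at random.

# ddCt: target gene measured against beta-actin, hypoxic vs control
fold = px.ddct_fold_change(
    ct_target_exp=20.0, ct_ref_exp=18.0,
    ct_target_ctrl=22.0, ct_ref_ctrl=18.0,
)
print(f"\nddCt fold change: {fold:.1f}x")
# ddCt = (20-18) - (22-18) = -2 cycles -> 2^2 = 4-fold up-regulation.
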