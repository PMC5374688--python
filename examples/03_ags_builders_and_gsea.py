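"""Build altered gene sets from an expression matrix; compare GSEA to NEA.

Simulates a two-group expression experiment with 10% differential genes,
derives per-contrast AGS with the fold-change builders, and shows the
mutation-table builder.  Then scores one AGS against a gene-set both by
overlap (Fisher GSEA) and through network edges (NEA) to illustrate why
the network view has more statistical power: the sets need not share a
single gene to be coupled.
"""

import pandas as pd

from netenrich import (
    GeneSet,
    GeneSetCollection,
    ScoreMatrix,
    SynthSpec,
    ags_significant,
    ags_top,
    gsea_render,
    make_expression_matrix,
    make_scalefree_network,
    mutations2ags,
    nea_render,
)

spec = SynthSpec(n_genes=2000, n_replicates=3, de_fraction=0.10, effect=4.0,
                 noise_sd=0.5, seed=42)
matrix, truth = make_expression_matrix(spec)

# contrast: mean log2 difference of group B over group A
diff = matrix.scores.filter(like="B_").mean(axis=1) - matrix.scores.filter(like="A_").mean(axis=1)
contrast = ScoreMatrix(pd.DataFrame({"B_vs_A": diff}))

top100 = ags_top(contrast, 100)
strict = ags_significant(contrast, cutoff=2.0)
print(f"top-100 builder: {len(top100['B_vs_A'])} genes (fixed size)")
print(f"|log2FC| > 2 builder: {len(strict['B_vs_A'])} genes (data-driven size)")
de = set(truth.loc[truth.is_de, "gene"])
recall = len(strict["B_vs_A"].members & de) / len(de)
print(f"recall of planted differential genes by the strict builder: {recall:.3f}")

muts = pd.DataFrame(
    [("patient1", "g000001"), ("patient1", "g000002"), ("patient2", "g000003")],
    columns=["sample", "gene"],
)
print(f"mutation builder: {[(s.set_id, len(s)) for s in mutations2ags(muts)]}")

# GSEA vs NEA on disjoint but network-coupled sets
net = make_scalefree_network(1000, 4, seed=3)
hub = max(net.degree, key=net.degree.get)
neighbours = sorted(net.neighbors(hub))[:20]
ags = GeneSetCollection([GeneSet("hub_set", frozenset([hub]))], role="AGS")
fgs = GeneSetCollection([GeneSet("neighbour_set", frozenset(neighbours))], role="FGS")

gsea_cell = gsea_render(ags, fgs, net=net).cells[0]
nea_cell = nea_render(net, ags, fgs).cells[0]
print()
print(f"shared genes: {gsea_cell.overlap}  ->  GSEA p = {gsea_cell.p:.3f}")
print(f"connecting edges: {nea_cell.n_edges} (expected {nea_cell.expected_edges:.2f})"
      f"  ->  NEA p = {nea_cell.p:.2e}")
print(
    "The two sets share no gene, so overlap-based GSEA sees nothing; "
    "network enrichment detects their coupling through edges."
)
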