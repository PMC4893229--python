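"""Duplication/loss scoring of gene-family trees against a species tree.

Each qualifying cluster's gene tree is reconciled with the species tree by
LCA mapping; duplications weigh 1.5 and losses 1.0.  A lower score per gene
means the family needs fewer evolutionary events to fit the species history,
i.e. it is phylogenetically more plausible.
"""

from genfamclust import FamilyPartition, score_cluster_set

species_tree = "((A,B),(C,D));"

clusters = FamilyPartition(
    {
        # family f1: one gene per species, congruent history
        "A_g1": "f1", "B_g2": "f1", "C_g3": "f1", "D_g4": "f1",
        # family f2: an extra duplicate in species A
        "A_h1": "f2", "A_h2": "f2", "B_h3": "f2", "C_h4": "f2", "D_h5": "f2",
        # too small to score (trees of < 4 genes always score 0)
        "A_t1": "f3", "B_t2": "f3",
    }
)
gene_trees = {
    "f1": "((A_g1,B_g2),(C_g3,D_g4));",
    "f2": "(((A_h1,A_h2),B_h3),(C_h4,D_h5));",
}

per_cluster, totals, missing = score_cluster_set(clusters, gene_trees, species_tree)
for label, res in sorted(per_cluster.items()):
    print(f"{label}: {res.duplications} duplications, {res.losses} losses, "
          f"D/L score {res.dl_score:.1f} over {res.n_genes} genes "
          f"({res.score_per_gene:.3f} per gene)")
print(f"TOTAL: {totals.duplications} duplications, {totals.losses} losses, "
      f"D/L {totals.dl_score:.1f} over {totals.n_genes} genes "
      f"= {totals.score_per_gene:.3f} per gene")
print()
print("f1 is congruent with the species tree (score 0); f2 pays 1.5 for the")
print("tandem duplication in species A; clusters smaller than 4 are skipped.")
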