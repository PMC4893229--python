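"""Gene-tree / species-tree reconciliation by LCA mapping.

Each gene-tree node is mapped to the lowest species-tree node that contains
all species under it (the LCA map).  A node is a duplication exactly when it
maps to the same species node as one of its children; otherwise it is a
speciation.  Losses are counted by the standard most-parsimonious
convention: for every gene-tree edge (u, v), the number of species-tree
edges between M(u) and M(v), minus one when u is a speciation (the branching
at M(u) itself is not a loss).  Losses above the gene-tree root are not
counted.  The LCA map minimizes both the duplication and the loss count, so
it realizes the most parsimonious reconciliation for any non-negative
weights.

The weighted D/L score is w_dup * duplications + w_loss * losses with the
customary defaults 1.5 and 1.0; a lower score per gene indicates a cluster
whose tree needs fewer evolutionary events to fit the species history.
"""

from __future__ import annotations

import warnings
from collections.abc import Callable, Mapping
from dataclasses import dataclass

import dendropy

from .io import FamilyPartition

__all__ = [
    "ReconciliationResult",
    "lca_reconcile",
    "dl_score",
    "score_cluster_set",
    "default_species_map",
]

DEFAULT_W_DUP = 1.5
DEFAULT_W_LOSS = 1.0


@dataclass(frozen=True)
class ReconciliationResult:
    duplications: int
    losses: int
    dl_score: float
    n_genes: int

    @property
    def score_per_gene(self) -> float:
        return self.dl_score / self.n_genes if self.n_genes else 0.0


def default_species_map(label: str) -> str:
    """Species id = leaf-label prefix before the first underscore."""
    return label.split("_", 1)[0]


def _as_tree(tree: dendropy.Tree | str) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)


def _check_binary(tree: dendropy.Tree, what: str) -> None:
    for node in tree.preorder_node_iter():
        n_children = len(node.child_nodes())
        if n_children not in (0, 2):
            raise ValueError(
                f"{what} must be rooted and binary; node with {n_children} "
                "children found (a trifurcating root usually means the tree "
                "is unrooted)"
            )


def _leaf_label(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    raise ValueError("unlabeled leaf in tree")


def lca_reconcile(
    gene_tree: dendropy.Tree | str,
    species_tree: dendropy.Tree | str,
    species_map: Callable[[str], str] = default_species_map,
) -> tuple[int, int]:
    """(duplications, losses) of the most parsimonious reconciliation.

    Gene-tree leaf labels are mapped to species via ``species_map``; an
    unmapped species label or a non-binary tree is fatal.
    """
    gtree = _as_tree(gene_tree)
    stree = _as_tree(species_tree)
    _check_binary(gtree, "gene tree")
    _check_binary(stree, "species tree")

    depth: dict[dendropy.Node, int] = {}
    parent: dict[dendropy.Node, dendropy.Node | None] = {}
    species_leaf: dict[str, dendropy.Node] = {}
    for node in stree.preorder_node_iter():
        parent[node] = node.parent_node
        depth[node] = 0 if node.parent_node is None else depth[node.parent_node] + 1
        if node.is_leaf():
            species_leaf[_leaf_label(node)] = node

    def lca(a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
        while depth[a] > depth[b]:
            a = parent[a]
        while depth[b] > depth[a]:
            b = parent[b]
        while a is not b:
            a, b = parent[a], parent[b]
        return a

    mapping: dict[dendropy.Node, dendropy.Node] = {}
    duplications = 0
    losses = 0
    for node in gtree.postorder_node_iter():
        if node.is_leaf():
            label = _leaf_label(node)
            sp = species_map(label)
            if sp not in species_leaf:
                raise KeyError(
                    f"gene-tree leaf {label!r} maps to species {sp!r}, "
                    "absent from the species tree"
                )
            mapping[node] = species_leaf[sp]
            continue
        c1, c2 = node.child_nodes()
        m = lca(mapping[c1], mapping[c2])
        mapping[node] = m
        is_dup = mapping[c1] is m or mapping[c2] is m
        if is_dup:
            duplications += 1
        for child in (c1, c2):
            dist = depth[mapping[child]] - depth[m]
            losses += dist if is_dup else dist - 1
    return duplications, losses


def dl_score(
    duplications: int,
    losses: int,
    w_dup: float = DEFAULT_W_DUP,
    w_loss: float = DEFAULT_W_LOSS,
) -> float:
    """Weighted duplication-loss score w_dup * D + w_loss * L."""
    if duplications < 0 or losses < 0:
        raise ValueError("event counts must be non-negative")
    return w_dup * duplications + w_loss * losses


def score_cluster_set(
    clusters: FamilyPartition,
    trees: Mapping[str, dendropy.Tree | str],
    species_tree: dendropy.Tree | str,
    min_size: int = 4,
    w_dup: float = DEFAULT_W_DUP,
    w_loss: float = DEFAULT_W_LOSS,
    species_map: Callable[[str], str] = default_species_map,
) -> tuple[dict[str, ReconciliationResult], ReconciliationResult, list[str]]:
    """Reconcile one gene tree per qualifying cluster and aggregate.

    Clusters smaller than ``min_size`` are skipped (their trees always score
    0).  Returns (per-cluster results, totals, labels missing a tree).
    Totals sum duplications, losses, weighted scores, and gene counts; the
    aggregate score per gene is total score / total genes.
    """
    stree = _as_tree(species_tree)
    per_cluster: dict[str, ReconciliationResult] = {}
    missing: list[str] = []
    tot_d = tot_l = tot_genes = 0
    for label in sorted(clusters.families):
        members = clusters.members(label)
        if len(members) < min_size:
            continue
        if label not in trees:
            missing.append(label)
            continue
        gtree = _as_tree(trees[label])
        d, l = lca_reconcile(gtree, stree, species_map)
        n_genes = sum(1 for _ in gtree.leaf_node_iter())
        per_cluster[label] = ReconciliationResult(
            duplications=d, losses=l, dl_score=dl_score(d, l, w_dup, w_loss),
            n_genes=n_genes,
        )
        tot_d += d
        tot_l += l
        tot_genes += n_genes
    if missing:
        warnings.warn(
            f"{len(missing)} clusters of size >= {min_size} lack a gene tree "
            "and were excluded from the totals",
            stacklevel=2,
        )
    totals = ReconciliationResult(
        duplications=tot_d, losses=tot_l,
        dl_score=dl_score(tot_d, tot_l, w_dup, w_loss), n_genes=tot_genes,
    )
    return per_cluster, totals, missing
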