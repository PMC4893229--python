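"""Scoring inferred partitions against a gold standard and against each other.

Provides per-family F-scores with member-weighted aggregation, pairwise
precision/recall over intra-family gene pairs, mutual information and
Jaccard similarity between two methods' homolog-pair sets, cluster coherence
classes (common / subset / superset / contradictory), and the local
syntenic-support check used to audit individual homolog pairs.

Pair counting works on unordered non-self pairs: a partition over n genes
induces n(n-1)/2 pairs, split into positives (intra-family) and negatives.
When two partitions cover different gene sets, all pair statistics are
computed on the intersection of the universes.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Iterable, Set
from dataclasses import dataclass, field

import pandas as pd

from .io import FamilyPartition, GeneOrderMap
from .nc import ScoreTable

__all__ = [
    "PairLabeling",
    "QualityReport",
    "CoherenceReport",
    "f_score",
    "partition_quality",
    "pairwise_pr",
    "pair_counts",
    "mutual_information",
    "jaccard",
    "intra_family_pairs",
    "coherence",
    "synteny_support",
]


def _comb2(n: int) -> int:
    return n * (n - 1) // 2


def pair_counts(n_genes: int, n_positive: int) -> tuple[int, int, int]:
    """(total, positive, negative) unordered pair counts for n genes.

    total = n(n-1)/2 and negatives = total - positives; raises if the
    positive count exceeds the total.
    """
    total = _comb2(n_genes)
    if not 0 <= n_positive <= total:
        raise ValueError(f"positive pairs {n_positive} outside [0, {total}]")
    return total, n_positive, total - n_positive


@dataclass(frozen=True)
class PairLabeling:
    """The yes/no homology labeling a partition induces on all gene pairs."""

    partition: FamilyPartition

    @property
    def n_genes(self) -> int:
        return len(self.partition)

    @property
    def n_pairs(self) -> int:
        return _comb2(self.n_genes)

    @property
    def n_positive(self) -> int:
        return sum(_comb2(len(m)) for m in self.partition.families.values())

    @property
    def n_negative(self) -> int:
        return self.n_pairs - self.n_positive

    def entropy(self) -> float:
        """Shannon entropy (nats) of the yes/no pair label."""
        return _entropy([self.n_positive, self.n_negative])


def f_score(cluster: Set[str], family: Set[str]) -> tuple[float, float, float]:
    """(precision, recall, F) of one cluster against one gold family.

    precision = |cluster & family| / |cluster|, recall = |cluster & family|
    / |family|, F their harmonic mean (0 when both are 0).
    """
    if not cluster or not family:
        raise ValueError("cluster and family must be non-empty")
    overlap = len(set(cluster) & set(family))
    p = overlap / len(cluster)
    r = overlap / len(family)
    f = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return p, r, f


@dataclass(frozen=True)
class QualityReport:
    """Per-gold-family best F-scores plus two aggregates.

    ``weighted`` is the member-weighted mean of best-F (weights = gold family
    sizes); ``unweighted`` the plain mean.  Both are reported because the
    choice of aggregation is a convention, not a given.
    """

    per_family: pd.DataFrame = field(repr=False)
    weighted: float
    unweighted: float


def partition_quality(partition: FamilyPartition, gold: FamilyPartition) -> QualityReport:
    """Best F over clusters for each gold family, with aggregates.

    Universes are intersected first; only clusters sharing a gene with the
    family can achieve nonzero F, so the search is restricted to those.
    """
    common = partition.genes & gold.genes
    if not common:
        raise ValueError("partition and gold standard share no genes")
    pred = partition.restricted_to(common)
    truth = gold.restricted_to(common)
    rows = []
    for label in sorted(truth.families):
        family = truth.members(label)
        best = (0.0, 0.0, 0.0, "")
        for cl_label in sorted({pred.family_of(g) for g in family}):
            p, r, f = f_score(pred.members(cl_label), family)
            if f > best[2]:
                best = (p, r, f, cl_label)
        rows.append(
            {
                "family": label,
                "size": len(family),
                "best_cluster": best[3],
                "precision": best[0],
                "recall": best[1],
                "f": best[2],
            }
        )
    df = pd.DataFrame(rows)
    weighted = float((df["f"] * df["size"]).sum() / df["size"].sum())
    unweighted = float(df["f"].mean())
    return QualityReport(per_family=df, weighted=weighted, unweighted=unweighted)


def _contingency(a: FamilyPartition, b: FamilyPartition) -> pd.DataFrame:
    common = sorted(a.genes & b.genes)
    df = pd.DataFrame(
        {
            "a": [a.family_of(g) for g in common],
            "b": [b.family_of(g) for g in common],
        }
    )
    return pd.crosstab(df["a"], df["b"])


def pairwise_pr(
    partition: FamilyPartition, gold: FamilyPartition
) -> tuple[float, float]:
    """Precision and recall over intra-family gene pairs.

    Positives are gold intra-family pairs; predicted positives are the
    partition's intra-cluster pairs; both restricted to the common universe.
    Vacuous denominators (no predicted / no gold positives) give 1.0.
    """
    table = _contingency(partition, gold)
    tp = int(sum(_comb2(int(v)) for v in table.to_numpy().ravel()))
    pred_pos = int(sum(_comb2(int(v)) for v in table.sum(axis=1)))
    gold_pos = int(sum(_comb2(int(v)) for v in table.sum(axis=0)))
    precision = tp / pred_pos if pred_pos else 1.0
    recall = tp / gold_pos if gold_pos else 1.0
    return precision, recall


def _entropy(counts: Iterable[int | float]) -> float:
    total = float(sum(counts))
    if total <= 0:
        return 0.0
    return -sum((c / total) * math.log(c / total) for c in counts if c > 0)


def mutual_information(label_a: PairLabeling, label_b: PairLabeling) -> float:
    """Mutual information (nats) between two pair labelings.

    M(X_A, X_B) = H(X_A) + H(X_B) - H(X_A, X_B), with entropies plugged in
    from the empirical joint distribution of (pair in A?, pair in B?) over
    all unordered pairs of the common universe.  Degenerate labelings (all
    pairs one class) give 0.  Tiny negative values from float cancellation
    are clipped to 0.
    """
    table = _contingency(label_a.partition, label_b.partition)
    n = int(table.to_numpy().sum())
    total = _comb2(n)
    if total == 0:
        return 0.0
    yy = int(sum(_comb2(int(v)) for v in table.to_numpy().ravel()))
    a_pos = int(sum(_comb2(int(v)) for v in table.sum(axis=1)))
    b_pos = int(sum(_comb2(int(v)) for v in table.sum(axis=0)))
    yn = a_pos - yy
    ny = b_pos - yy
    nn = total - yy - yn - ny
    h_a = _entropy([a_pos, total - a_pos])
    h_b = _entropy([b_pos, total - b_pos])
    h_ab = _entropy([yy, yn, ny, nn])
    return max(0.0, h_a + h_b - h_ab)


def _canonical_pairs(pairs: Iterable[tuple[str, str]]) -> set[tuple[str, str]]:
    return {tuple(sorted(p)) for p in pairs}


def jaccard(pairs_a: Iterable[tuple[str, str]], pairs_b: Iterable[tuple[str, str]]) -> float:
    """|A & B| / |A | B| over homolog-pair sets; 1.0 (with a warning) when
    both sets are empty."""
    a = _canonical_pairs(pairs_a)
    b = _canonical_pairs(pairs_b)
    union = a | b
    if not union:
        warnings.warn("Jaccard of two empty pair sets defined as 1.0", stacklevel=2)
        return 1.0
    return len(a & b) / len(union)


def intra_family_pairs(partition: FamilyPartition) -> set[tuple[str, str]]:
    """All unordered intra-family gene pairs of a partition."""
    pairs: set[tuple[str, str]] = set()
    for members in partition.families.values():
        ordered = sorted(members)
        for i, g1 in enumerate(ordered):
            for g2 in ordered[i + 1 :]:
                pairs.add((g1, g2))
    return pairs


@dataclass(frozen=True)
class CoherenceReport:
    """Classification of every A-cluster against partition B.

    classes: per A-cluster label, one of 'common', 'subset', 'superset',
    'contradictory'.  counts / gene_counts tally clusters and their member
    genes per class; fractions normalize the cluster counts.
    """

    classes: dict[str, str] = field(repr=False)
    counts: dict[str, int]
    gene_counts: dict[str, int]

    @property
    def fractions(self) -> dict[str, float]:
        total = sum(self.counts.values())
        return {k: v / total for k, v in self.counts.items()} if total else {}


def coherence(part_a: FamilyPartition, part_b: FamilyPartition) -> CoherenceReport:
    """Classify each A-cluster as common, subset, superset or contradictory.

    common: identical to a B-cluster; subset: strictly inside one B-cluster;
    superset: the disjoint union of two or more whole B-clusters;
    contradictory: anything else (the two methods genuinely disagree).
    B-clusters are taken whole: a B-cluster reaching outside the A-cluster is
    a disagreement even when the extra genes are absent from A's universe.
    """
    a, b = part_a, part_b
    classes: dict[str, str] = {}
    counts = {"common": 0, "subset": 0, "superset": 0, "contradictory": 0}
    gene_counts = dict(counts)
    for label, members in sorted(a.families.items()):
        b_labels = {b.family_of(g) for g in members if g in b}
        b_sets = [b.members(lb) for lb in b_labels]
        covered = set().union(*b_sets) if b_sets else set()
        if not members <= covered:
            kind = "contradictory"  # members unknown to B cannot agree
        elif len(b_sets) == 1:
            kind = "common" if b_sets[0] == members else "subset"
        elif all(s <= members for s in b_sets):
            kind = "superset"
        else:
            kind = "contradictory"
        classes[label] = kind
        counts[kind] += 1
        gene_counts[kind] += len(members)
    return CoherenceReport(classes=classes, counts=counts, gene_counts=gene_counts)


def synteny_support(
    pair: tuple[str, str],
    order: GeneOrderMap,
    hits: ScoreTable,
    window: int = 5,
) -> bool:
    """True iff a similarity hit links the two genes' neighborhoods.

    Looks at up to ``window`` genes upstream and downstream of each gene and
    reports whether any neighbor of one has a nonzero hit with any neighbor
    of the other — the local gene-order audit applied to curated family
    pairs.
    """
    g1, g2 = pair
    n1 = order.neighborhood(g1, window)
    n2 = order.neighborhood(g2, window)
    for a in n1:
        partners = hits.partners(a)
        for b in n2:
            if a != b and partners.get(b, 0.0) > 0.0:
                return True
    return False
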