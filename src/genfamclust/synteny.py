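"""Local synteny (SyS) and synteny correlation (SyC) scores.

SyS(g1, g2) is the best NC between any two genes drawn from the k-gene
neighborhoods of g1 and g2 — direct evidence that the two loci sit in
similar gene-order context.  SyC(g1, g2) correlates the SyS profiles of the
two genes over their shared NC-hit set H, pooling synteny evidence across
homologous regions from multiple species (and so a range of divergence
times), which makes it more robust than a single SyS value.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

from .io import GeneOrderMap
from .nc import NCGraph

__all__ = [
    "SyntenyParams",
    "PairSynteny",
    "SyntenyGraph",
    "neighborhood",
    "sys_score",
    "nc_hits",
    "syc_score",
    "synteny_all",
]


@dataclass(frozen=True)
class SyntenyParams:
    """Tunables for the synteny stage.

    k: neighborhood radius in genes (upstream and downstream).
    beta: minimum NC both for membership in ncHits (>= beta) and for
        selecting candidate pairs (> beta, strict), exactly as the two
        comparisons are defined.
    exclude_query_pair: optionally drop the queried genes themselves from
        each other's neighborhood support (off by default; for sensitivity
        analysis).
    """

    k: int = 5
    beta: float = 0.3
    exclude_query_pair: bool = False

    def __post_init__(self) -> None:
        if self.k < 0 or int(self.k) != self.k:
            raise ValueError("k must be a non-negative integer")
        if not -1.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [-1, 1]")


@dataclass(frozen=True)
class PairSynteny:
    nc: float
    sys: float
    syc: float
    h_size: int


class SyntenyGraph:
    """Per-pair SyS/SyC records, symmetric, keyed by sorted gene pairs."""

    def __init__(self, records: Mapping[tuple[str, str], PairSynteny] | None = None):
        self._records: dict[tuple[str, str], PairSynteny] = dict(records or {})

    @staticmethod
    def _key(g1: str, g2: str) -> tuple[str, str]:
        return (g1, g2) if g1 <= g2 else (g2, g1)

    def add(self, g1: str, g2: str, record: PairSynteny) -> None:
        self._records[self._key(g1, g2)] = record

    def get(self, g1: str, g2: str) -> PairSynteny | None:
        return self._records.get(self._key(g1, g2))

    def items(self):
        return self._records.items()

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SyntenyGraph) and self._records == other._records


def neighborhood(order: GeneOrderMap, g: str, k: int) -> list[str]:
    """Neighbor genes of g at index distance 1..k on its contig."""
    return order.neighborhood(g, k)


def sys_score(
    nc: NCGraph,
    order: GeneOrderMap,
    g1: str,
    g2: str,
    params: SyntenyParams | None = None,
    _memo: dict | None = None,
) -> float:
    """Maximum NC over the Cartesian product of the two k-neighborhoods.

    0.0 when either neighborhood is empty or no NC edge links the two
    neighborhoods.
    """
    params = params or SyntenyParams()
    key = (g1, g2) if g1 <= g2 else (g2, g1)
    if _memo is not None and key in _memo:
        return _memo[key]
    n1 = order.neighborhood(g1, params.k)
    n2 = set(order.neighborhood(g2, params.k))
    if params.exclude_query_pair:
        n1 = [a for a in n1 if a != g2]
        n2.discard(g1)
    best = 0.0
    for a in n1:
        partners = nc.partners(a)
        if len(partners) < len(n2):
            for b, v in partners.items():
                if b in n2 and v > best:
                    best = v
        else:
            for b in n2:
                v = partners.get(b)
                if v is not None and v > best:
                    best = v
    if _memo is not None:
        _memo[key] = best
    return best


def nc_hits(nc: NCGraph, g: str, beta: float) -> set[str]:
    """All genes i with NC(g, i) >= beta (inclusive, as defined)."""
    return {i for i, v in nc.partners(g).items() if v >= beta}


def _pearson(xs: list[float], ys: list[float]) -> tuple[float, bool]:
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    vx = sum((x - mx) ** 2 for x in xs)
    vy = sum((y - my) ** 2 for y in ys)
    if vx <= 1e-15 or vy <= 1e-15:
        return 0.0, True
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    value = cov / (vx * vy) ** 0.5
    return max(-1.0, min(1.0, value)), False


def syc_score(
    nc: NCGraph,
    order: GeneOrderMap,
    g1: str,
    g2: str,
    params: SyntenyParams | None = None,
    _memo: dict | None = None,
) -> tuple[float, int]:
    """SyC and |H|: Pearson correlation of the SyS vectors over H.

    H is the intersection of the two genes' NC-hit sets (restricted to genes
    with known coordinates).  Returns (0.0, |H|) when |H| < 2 or either SyS
    vector is constant — correlation is undefined there and 0 is the neutral
    value under the decision boundary.
    """
    params = params or SyntenyParams()
    shared = nc_hits(nc, g1, params.beta) & nc_hits(nc, g2, params.beta)
    shared = {i for i in shared if i in order}
    h = sorted(shared)
    if len(h) < 2:
        return 0.0, len(h)
    xs = [sys_score(nc, order, g1, i, params, _memo) for i in h]
    ys = [sys_score(nc, order, g2, i, params, _memo) for i in h]
    value, _ = _pearson(xs, ys)
    return value, len(h)


def synteny_all(
    nc: NCGraph,
    order: GeneOrderMap,
    params: SyntenyParams | None = None,
    candidate_pairs: Iterable[tuple[str, str]] | None = None,
) -> SyntenyGraph:
    """SyS and SyC for every NC edge with nc > beta (strict).

    Candidate genes must have known coordinates; NC edges touching a gene
    absent from the gene-order map are skipped.  SyS values needed for the
    SyC vectors are memoized across pairs.
    """
    params = params or SyntenyParams()
    if candidate_pairs is None:
        candidate_pairs = [
            (g1, g2) for g1, g2, v in nc.edges() if v > params.beta
        ]
    memo: dict[tuple[str, str], float] = {}
    graph = SyntenyGraph()
    for g1, g2 in sorted(tuple(sorted(p)) for p in candidate_pairs):
        if g1 not in order or g2 not in order:
            continue
        sys_v = sys_score(nc, order, g1, g2, params, memo)
        syc_v, h_size = syc_score(nc, order, g1, g2, params, memo)
        graph.add(g1, g2, PairSynteny(nc=nc.nc(g1, g2), sys=sys_v, syc=syc_v, h_size=h_size))
    return graph
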