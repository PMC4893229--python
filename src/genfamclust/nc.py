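"""Score normalization and Neighborhood Correlation (NC).

NC treats each gene as a vector of normalized similarity scores against the
whole reference database (query plus reference genes) and scores a candidate
pair by the Pearson correlation of the two vectors.  Two genes whose hit
profiles agree — even when their direct alignment is weak, as happens for
multidomain proteins — receive a high NC.

Missing hits contribute 0 to the vectors; the sparse computation below
corrects means and variances for the implicit zeros, so it agrees exactly
with a dense, zero-filled Pearson computation.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Iterable, Mapping, Sequence

from .io import HitRecord

__all__ = ["ScoreTable", "NCGraph", "normalize_scores", "nc_score", "nc_all"]

#: default retention threshold, the floor used for NC-only homology calling
DEFAULT_NC_MIN = 0.05

# relative variance floor: a vector whose variance falls below this (relative
# to its raw second moment) is treated as degenerate and contributes NC = 0
_VAR_TOL = 1e-12


class ScoreTable:
    """Sparse symmetric table of normalized similarity scores in [0, 1].

    ``scores`` maps gene -> {partner -> score}, symmetric and including the
    self entry (1.0 whenever a self hit exists).  ``universe`` is the ordered
    reference gene set of size N over which NC vectors are defined; it
    defaults to the genes present in the table but may be widened (e.g. with
    genes known only from annotation).
    """

    def __init__(
        self,
        scores: Mapping[str, Mapping[str, float]],
        universe: Sequence[str] | None = None,
    ):
        self._scores: dict[str, dict[str, float]] = {
            g: dict(partners) for g, partners in scores.items()
        }
        if universe is None:
            universe = sorted(self._scores)
        self.universe: tuple[str, ...] = tuple(universe)
        missing = set(self._scores) - set(self.universe)
        if missing:
            raise ValueError(f"scored genes missing from universe: {sorted(missing)[:5]}")

    @property
    def n(self) -> int:
        """Size of the reference database N."""
        return len(self.universe)

    def genes(self) -> list[str]:
        return sorted(self._scores)

    def score(self, g1: str, g2: str) -> float:
        """Normalized score for the pair, 0.0 for non-hits."""
        return self._scores.get(g1, {}).get(g2, 0.0)

    def self_score(self, g: str) -> float:
        return self.score(g, g)

    def partners(self, g: str) -> Mapping[str, float]:
        return self._scores.get(g, {})

    def pairs(self) -> Iterable[tuple[str, str]]:
        """Unordered non-self pairs with a nonzero score, each once."""
        for g1 in sorted(self._scores):
            for g2 in sorted(self._scores[g1]):
                if g1 < g2:
                    yield (g1, g2)


def normalize_scores(hits: Iterable[HitRecord]) -> ScoreTable:
    """Symmetrize raw bit scores and normalize by the larger self score.

    For each unordered pair the raw score is the maximum over both hit
    directions and duplicates; the normalized score is
    ``s(g1,g2) / max(s(g1,g1), s(g2,g2))``, clamped to [0, 1].  A gene with
    pair hits but no self hit falls back to its maximum observed raw score
    as self score (with a warning).
    """
    raw: dict[tuple[str, str], float] = {}
    selfs: dict[str, float] = {}
    maxseen: dict[str, float] = {}
    genes: set[str] = set()
    n_hits = 0
    for hit in hits:
        n_hits += 1
        q, s = hit.query_id, hit.subject_id
        genes.update((q, s))
        maxseen[q] = max(maxseen.get(q, 0.0), hit.bit_score)
        maxseen[s] = max(maxseen.get(s, 0.0), hit.bit_score)
        if q == s:
            selfs[q] = max(selfs.get(q, 0.0), hit.bit_score)
        else:
            pair = (q, s) if q < s else (s, q)
            raw[pair] = max(raw.get(pair, 0.0), hit.bit_score)
    if n_hits == 0:
        raise ValueError("no hits to normalize")
    no_self = sorted(g for g in genes if g not in selfs)
    if no_self:
        warnings.warn(
            f"{len(no_self)} genes lack a self hit; falling back to their "
            f"maximum observed raw score (first: {no_self[0]!r})",
            stacklevel=2,
        )
        for g in no_self:
            selfs[g] = maxseen[g]
    scores: dict[str, dict[str, float]] = {g: {g: 1.0} for g in genes}
    for (g1, g2), value in raw.items():
        norm = min(1.0, value / max(selfs[g1], selfs[g2]))
        scores[g1][g2] = norm
        scores[g2][g1] = norm
    return ScoreTable(scores)


class NCGraph:
    """Symmetric graph of gene pairs with their NC values."""

    def __init__(self, nc_min: float | None = None):
        self._adj: dict[str, dict[str, float]] = {}
        self.nc_min = nc_min

    def add(self, g1: str, g2: str, value: float) -> None:
        self._adj.setdefault(g1, {})[g2] = value
        self._adj.setdefault(g2, {})[g1] = value

    def has_edge(self, g1: str, g2: str) -> bool:
        return g2 in self._adj.get(g1, {})

    def nc(self, g1: str, g2: str, default: float = 0.0) -> float:
        return self._adj.get(g1, {}).get(g2, default)

    def partners(self, g: str) -> Mapping[str, float]:
        return self._adj.get(g, {})

    def genes(self) -> list[str]:
        return sorted(self._adj)

    def edges(self) -> Iterable[tuple[str, str, float]]:
        for g1 in self._adj:
            for g2, v in self._adj[g1].items():
                if g1 < g2:
                    yield (g1, g2, v)

    def __len__(self) -> int:
        return sum(len(p) for p in self._adj.values()) // 2


def _moments(table: ScoreTable) -> tuple[dict[str, float], dict[str, float]]:
    sums = {g: math.fsum(table.partners(g).values()) for g in table.genes()}
    sumsqs = {
        g: math.fsum(v * v for v in table.partners(g).values()) for g in table.genes()
    }
    return sums, sumsqs


def _pair_nc(
    table: ScoreTable,
    sums: Mapping[str, float],
    sumsqs: Mapping[str, float],
    g1: str,
    g2: str,
) -> tuple[float, bool]:
    """Pearson correlation of the zero-filled score vectors; (value, degenerate)."""
    n = table.n
    s1, s2 = sums.get(g1, 0.0), sums.get(g2, 0.0)
    q1, q2 = sumsqs.get(g1, 0.0), sumsqs.get(g2, 0.0)
    var1 = q1 - s1 * s1 / n
    var2 = q2 - s2 * s2 / n
    if var1 <= _VAR_TOL * max(1.0, q1) or var2 <= _VAR_TOL * max(1.0, q2):
        return 0.0, True
    p1, p2 = table.partners(g1), table.partners(g2)
    if len(p2) < len(p1):
        p1, p2 = p2, p1
    dot = math.fsum(v * p2[i] for i, v in p1.items() if i in p2)
    cov = dot - s1 * s2 / n
    value = cov / math.sqrt(var1 * var2)
    return max(-1.0, min(1.0, value)), False


def nc_score(table: ScoreTable, g1: str, g2: str) -> float:
    """NC of one pair: Pearson correlation over the full universe of size N.

    Zero-variance (all-zero or constant) vectors yield 0.0 by convention —
    a gene similar to nothing carries no correlation signal.
    """
    for g in (g1, g2):
        if g not in table.universe:
            raise KeyError(f"gene {g!r} not in the score-table universe")
    sums, sumsqs = _moments(table)
    value, _ = _pair_nc(table, sums, sumsqs, g1, g2)
    return value


def nc_all(
    table: ScoreTable,
    candidate_pairs: Iterable[tuple[str, str]] | None = None,
    nc_min: float = DEFAULT_NC_MIN,
) -> NCGraph:
    """Compute NC for candidate pairs and retain edges with nc >= nc_min.

    Candidates default to all pairs with a nonzero similarity hit (NC is
    evaluated per hit, never for all N^2 pairs).  Per-gene means and
    variances are precomputed once, so the cost is O(|pairs| * avg hits).
    """
    if candidate_pairs is None:
        candidate_pairs = table.pairs()
    sums, sumsqs = _moments(table)
    graph = NCGraph(nc_min=nc_min)
    n_candidates = 0
    for g1, g2 in candidate_pairs:
        n_candidates += 1
        value, _ = _pair_nc(table, sums, sumsqs, g1, g2)
        if value >= nc_min:
            graph.add(g1, g2, value)
    if n_candidates == 0:
        warnings.warn("empty candidate pair set: NC graph is empty", stacklevel=2)
    return graph
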