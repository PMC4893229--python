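"""The quadratic homology decision boundary.

A candidate pair is scored as

    h = NC^2 + 0.25 * SyC^2 - 0.25

and called homologous when h > 0 (strictly).  The zero set is the ellipse
NC^2 + 0.25 SyC^2 = 0.25: with no synteny evidence (SyC = 0) the rule
degenerates to |NC| > 0.5, the classic NC-only homology threshold, while
strong synteny correlation lets pairs with much weaker NC through.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass

from .synteny import SyntenyGraph

__all__ = ["DecisionParams", "PairCall", "HomologyGraph", "decision_value", "infer_homologs"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DecisionParams:
    """Constants of the decision boundary; defaults reproduce the published rule."""

    syc_weight: float = 0.25
    intercept: float = 0.25


@dataclass(frozen=True)
class PairCall:
    nc: float
    sys: float
    syc: float
    h: float
    call: bool


class HomologyGraph:
    """Per-pair scores plus the homolog call, keyed by sorted gene pairs."""

    def __init__(self, records: Mapping[tuple[str, str], PairCall] | None = None):
        self._records: dict[tuple[str, str], PairCall] = dict(records or {})

    @staticmethod
    def _key(g1: str, g2: str) -> tuple[str, str]:
        return (g1, g2) if g1 <= g2 else (g2, g1)

    def add(self, g1: str, g2: str, record: PairCall) -> None:
        self._records[self._key(g1, g2)] = record

    def get(self, g1: str, g2: str) -> PairCall | None:
        return self._records.get(self._key(g1, g2))

    def items(self):
        return self._records.items()

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self._records)

    def called_pairs(self) -> list[tuple[str, str]]:
        return sorted(p for p, rec in self._records.items() if rec.call)

    @property
    def n_called(self) -> int:
        return sum(1 for rec in self._records.values() if rec.call)

    def __len__(self) -> int:
        return len(self._records)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, HomologyGraph) and self._records == other._records


def decision_value(nc: float, syc: float, params: DecisionParams | None = None) -> float:
    """h = nc^2 + syc_weight * syc^2 - intercept; pure and deterministic."""
    params = params or DecisionParams()
    return nc * nc + params.syc_weight * syc * syc - params.intercept


def infer_homologs(
    syn: SyntenyGraph, params: DecisionParams | None = None
) -> HomologyGraph:
    """Apply the decision boundary to every pair of a synteny graph.

    Pairs never evaluated by the synteny stage (NC <= beta) are absent, not
    auto-negative, so NC-only baselines remain possible downstream.
    """
    params = params or DecisionParams()
    graph = HomologyGraph()
    for (g1, g2), rec in syn.items():
        h = decision_value(rec.nc, rec.syc, params)
        graph.add(g1, g2, PairCall(nc=rec.nc, sys=rec.sys, syc=rec.syc, h=h, call=h > 0.0))
    logger.info(
        "homology decision: %d of %d pairs called homologous",
        graph.n_called, len(graph),
    )
    return graph
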