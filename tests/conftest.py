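"""Shared fixtures: tiny hand-built instances every stage can be checked on."""

from __future__ import annotations

import pytest
from hypothesis import settings

from genfamclust import FamilyPartition, GeneOrderMap, HitRecord, ScoreTable

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def toy_hits() -> list[HitRecord]:
    """Two small families {a1,a2,b1} and {c1}; asymmetric directions included."""
    return [
        HitRecord("a1", "a1", 100.0),
        HitRecord("a2", "a2", 80.0),
        HitRecord("b1", "b1", 110.0),
        HitRecord("c1", "c1", 90.0),
        HitRecord("a1", "a2", 50.0),
        HitRecord("a2", "a1", 44.0),
        HitRecord("a1", "b1", 40.0),
        HitRecord("b1", "a1", 44.0),
        HitRecord("a2", "b1", 30.0),
    ]


@pytest.fixture
def toy_order() -> GeneOrderMap:
    """Two species, one contig each, four genes per contig in matched order."""
    rows = []
    for sp in ("A", "B"):
        for i, fam in enumerate(("x", "y", "z", "w")):
            rows.append((f"{sp}_{fam}", sp, "c1", float(i * 10)))
    return GeneOrderMap(rows)


@pytest.fixture
def toy_partition() -> FamilyPartition:
    return FamilyPartition(
        {"a1": "F1", "a2": "F1", "b1": "F2", "b2": "F2", "c1": "F3"}
    )


def make_score_table(
    pair_scores: dict[tuple[str, str], float], universe=None
) -> ScoreTable:
    """Symmetric ScoreTable from unordered pair scores, self scores 1.0."""
    genes = {g for p in pair_scores for g in p}
    scores: dict[str, dict[str, float]] = {g: {g: 1.0} for g in genes}
    for (g1, g2), v in pair_scores.items():
        scores[g1][g2] = v
        scores[g2][g1] = v
    return ScoreTable(scores, universe=universe)
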