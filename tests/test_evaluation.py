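"""F-scores, pair statistics, mutual information, Jaccard, coherence, synteny support."""

from __future__ import annotations

import math

import numpy as np
import pytest

from genfamclust import (
    FamilyPartition,
    GeneOrderMap,
    PairLabeling,
    coherence,
    f_score,
    intra_family_pairs,
    jaccard,
    mutual_information,
    pair_counts,
    pairwise_pr,
    partition_quality,
    synteny_support,
)

from conftest import make_score_table


def partition_of(groups: list[set[str]]) -> FamilyPartition:
    return FamilyPartition.from_clusters(groups)


def random_partition(rng, genes, n_families):
    labels = rng.integers(n_families, size=len(genes))
    return FamilyPartition({g: f"R{l}" for g, l in zip(genes, labels)})


class TestFScore:
    def test_identical_sets(self):
        assert f_score({"a", "b", "c"}, {"a", "b", "c"}) == (1.0, 1.0, 1.0)

    def test_disjoint_sets(self):
        assert f_score({"a"}, {"b"}) == (0.0, 0.0, 0.0)

    def test_hand_computed_two_thirds(self):
        p, r, f = f_score({"a", "b", "c"}, {"b", "c", "d"})
        assert (p, r, f) == pytest.approx((2 / 3, 2 / 3, 2 / 3))

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            f_score(set(), {"a"})


class TestPartitionQuality:
    def test_identical_partitions_score_one(self, toy_partition):
        report = partition_quality(toy_partition, toy_partition)
        assert report.weighted == pytest.approx(1.0)
        assert report.unweighted == pytest.approx(1.0)

    def test_everything_merged_closed_form(self):
        # one cluster of 2m genes vs two gold families of size m:
        # best F per family = 2m / (m + 2m) = 2/3
        m = 5
        genes = [f"g{i}" for i in range(2 * m)]
        merged = FamilyPartition({g: "all" for g in genes})
        gold = partition_of([set(genes[:m]), set(genes[m:])])
        report = partition_quality(merged, gold)
        assert report.weighted == pytest.approx(2 / 3)
        assert report.unweighted == pytest.approx(2 / 3)

    def test_all_singletons_closed_form(self):
        # singleton clusters vs one family of size f: best F = 2 / (1 + f)
        f = 7
        genes = [f"g{i}" for i in range(f)]
        singletons = partition_of([{g} for g in genes])
        gold = FamilyPartition({g: "fam" for g in genes})
        report = partition_quality(singletons, gold)
        assert report.weighted == pytest.approx(2 / (1 + f))


class TestPairCounts:
    def test_sum_identity_for_random_partitions(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(40)]
        for k in (1, 3, 10):
            lab = PairLabeling(random_partition(rng, genes, k))
            assert lab.n_positive + lab.n_negative == 40 * 39 // 2

    def test_pair_counts_arithmetic(self):
        total, pos, neg = pair_counts(5, 4)
        assert (total, pos, neg) == (10, 4, 6)
        with pytest.raises(ValueError):
            pair_counts(3, 5)

    def test_identical_partitions_have_perfect_pr(self, toy_partition):
        assert pairwise_pr(toy_partition, toy_partition) == (1.0, 1.0)

    def test_pairwise_pr_hand_case(self):
        pred = partition_of([{"a", "b", "c"}, {"d"}])
        gold = partition_of([{"a", "b"}, {"c", "d"}])
        precision, recall = pairwise_pr(pred, gold)
        assert precision == pytest.approx(1 / 3)  # only a-b of 3 predicted
        assert recall == pytest.approx(1 / 2)  # a-b of {a-b, c-d}


class TestMutualInformation:
    @staticmethod
    def plugin_mi(yy, yn, ny, nn):
        """Independent oracle: direct plug-in over the 2x2 joint table."""
        total = yy + yn + ny + nn
        mi = 0.0
        marg_a = {True: yy + yn, False: ny + nn}
        marg_b = {True: yy + ny, False: yn + nn}
        joint = {(True, True): yy, (True, False): yn, (False, True): ny, (False, False): nn}
        for (a, b), c in joint.items():
            if c == 0:
                continue
            p = c / total
            mi += p * math.log(p / (marg_a[a] / total * marg_b[b] / total))
        return mi

    def test_self_information_equals_entropy(self):
        part = partition_of([{"a", "b", "c"}, {"d", "e"}, {"f"}])
        lab = PairLabeling(part)
        assert mutual_information(lab, lab) == pytest.approx(lab.entropy())

    def test_degenerate_labeling_gives_zero(self):
        genes = [f"g{i}" for i in range(6)]
        singletons = partition_of([{g} for g in genes])  # no positive pairs
        other = partition_of([set(genes[:3]), set(genes[3:])])
        assert mutual_information(PairLabeling(singletons), PairLabeling(other)) == 0.0

    def test_matches_plugin_oracle_on_random_partitions(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(30)]
        for _ in range(5):
            a = random_partition(rng, genes, 4)
            b = random_partition(rng, genes, 3)
            pa = intra_family_pairs(a)
            pb = intra_family_pairs(b)
            total = len(genes) * 29 // 2
            yy = len(pa & pb)
            yn = len(pa) - yy
            ny = len(pb) - yy
            nn = total - yy - yn - ny
            expected = self.plugin_mi(yy, yn, ny, nn)
            assert mutual_information(PairLabeling(a), PairLabeling(b)) == pytest.approx(
                expected, abs=1e-12
            )

    def test_bounded_by_min_marginal_entropy_and_symmetric(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(25)]
        for _ in range(8):
            la = PairLabeling(random_partition(rng, genes, 3))
            lb = PairLabeling(random_partition(rng, genes, 5))
            mi = mutual_information(la, lb)
            assert 0.0 <= mi <= min(la.entropy(), lb.entropy()) + 1e-12
            assert mi == pytest.approx(mutual_information(lb, la), abs=1e-12)


class TestJaccard:
    def test_identical_sets(self):
        pairs = {("a", "b"), ("c", "d")}
        assert jaccard(pairs, pairs) == 1.0

    def test_disjoint_nonempty(self):
        assert jaccard({("a", "b")}, {("c", "d")}) == 0.0

    def test_direct_set_arithmetic(self):
        a = {(f"g{i}", f"h{i}") for i in range(10)}  # 10 pairs
        b = set(list(a)[:3]) | {(f"x{i}", f"y{i}") for i in range(2)}  # 3 shared + 2
        # |intersection| = 3, |union| = 12
        assert jaccard(a, b) == pytest.approx(3 / 12)

    def test_orientation_insensitive(self):
        assert jaccard({("b", "a")}, {("a", "b")}) == 1.0

    def test_both_empty_is_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert jaccard(set(), set()) == 1.0

    def test_invariant_under_gene_relabeling(self):
        a = {("a", "b"), ("b", "c")}
        b = {("a", "b")}
        ren = {"a": "x", "b": "y", "c": "z"}
        a2 = {(ren[p], ren[q]) for p, q in a}
        b2 = {(ren[p], ren[q]) for p, q in b}
        assert jaccard(a, b) == jaccard(a2, b2)


class TestCoherence:
    def test_identical_partitions_fully_common(self, toy_partition):
        report = coherence(toy_partition, toy_partition)
        assert report.counts["common"] == toy_partition.n_families
        assert report.counts["contradictory"] == 0

    def test_big_cluster_over_split_gold_is_superset(self):
        a = partition_of([{"a", "b", "c", "d"}])
        b = partition_of([{"a", "b"}, {"c", "d"}])
        report = coherence(a, b)
        assert report.classes == {"F000001": "superset"}

    def test_contradictory_by_definition(self):
        a = partition_of([{"a", "b"}])
        b = partition_of([{"a", "c"}, {"b"}])
        report = coherence(a, b)
        assert report.classes[a.family_of("a")] == "contradictory"

    def test_subset_is_strict_containment(self):
        a = partition_of([{"a", "b"}, {"c"}])
        b = partition_of([{"a", "b", "c"}])
        report = coherence(a, b)
        assert report.counts == {"common": 0, "subset": 2, "superset": 0, "contradictory": 0}
        assert report.gene_counts["subset"] == 3

    def test_classes_are_exhaustive(self):
        rng = np.random.default_rng(31)
        genes = [f"g{i}" for i in range(20)]
        a = random_partition(rng, genes, 5)
        b = random_partition(rng, genes, 4)
        report = coherence(a, b)
        assert sum(report.counts.values()) == a.n_families
        assert sum(report.gene_counts.values()) == len(genes)


class TestSyntenySupport:
    def make_order(self, n=21):
        rows = []
        for sp in ("A", "B"):
            for i in range(n):
                rows.append((f"{sp}{i}", sp, "c1", float(i)))
        return GeneOrderMap(rows)

    def test_conserved_block_with_one_neighbor_hit(self):
        order = self.make_order()
        hits = make_score_table({("A9", "B11"): 0.4})
        assert synteny_support(("A10", "B10"), order, hits) is True

    def test_isolated_singleton_contigs_unsupported(self):
        order = GeneOrderMap([("a", "A", "c1", 0.0), ("b", "B", "c1", 0.0)])
        hits = make_score_table({("a", "b"): 0.9})
        assert synteny_support(("a", "b"), order, hits) is False

    def test_matches_exhaustive_neighbor_scan(self):
        rng = np.random.default_rng(3)
        order = self.make_order()
        genes = [f"{sp}{i}" for sp in ("A", "B") for i in range(21)]
        pair_scores = {}
        for _ in range(60):
            g1, g2 = rng.choice(genes, size=2, replace=False)
            pair_scores[(str(g1), str(g2))] = float(rng.uniform(0.05, 1.0))
        hits = make_score_table(pair_scores, universe=genes)
        for center in (("A10", "B10"), ("A2", "B18"), ("A0", "B0")):
            expected = any(
                hits.score(a, b) > 0 and a != b
                for a in order.neighborhood(center[0], 5)
                for b in order.neighborhood(center[1], 5)
            )
            assert synteny_support(center, order, hits) is expected
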