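"""Readers and writers for the external formats used by the pipeline.

Handles BLAST tabular hit lists (outfmt 6 / -m8), gene-order tables (TSV or
GFF3), gold-standard family tables, and the TSV outputs written by each
pipeline stage.  All identifiers are treated as opaque, case-sensitive
strings.  Output row order is deterministic (lexicographic by gene id) so
that write -> read -> write round trips are byte-identical.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "HitRecord",
    "BlastDialect",
    "GeneOrderMap",
    "FamilyPartition",
    "read_blast_tabular",
    "read_gene_order",
    "read_gene_order_gff3",
    "read_family_table",
    "write_clusters",
    "write_homolog_pairs",
    "read_homolog_pairs",
    "write_nc_table",
    "read_nc_table",
    "write_synteny_table",
    "read_synteny_table",
]


@dataclass(frozen=True)
class HitRecord:
    """One pairwise similarity hit: query, subject, raw bit score.

    The bit score is the raw (un-normalized) alignment score; normalization
    against self-scores happens downstream.
    """

    query_id: str
    subject_id: str
    bit_score: float
    e_value: float | None = None

    def __post_init__(self) -> None:
        if not self.query_id or not self.subject_id:
            raise ValueError("hit identifiers must be non-empty")
        if not self.bit_score > 0:
            raise ValueError(f"bit score must be positive, got {self.bit_score!r}")


@dataclass(frozen=True)
class BlastDialect:
    """Column selection for a tab-separated hit file (0-based indices).

    Defaults match 12-column BLAST outfmt 6 / -m8: query and subject first,
    e-value in column 11, bit score last.
    """

    query_col: int = 0
    subject_col: int = 1
    bit_score_col: int = 11
    e_value_col: int | None = 10


def read_blast_tabular(
    path: str | Path, dialect: BlastDialect | None = None
) -> list[HitRecord]:
    """Parse a BLAST tabular file into hit records.

    Lines that fail to parse are counted and reported in a warning; duplicate
    (query, subject) lines are retained so downstream symmetrization can take
    the maximum over directions.  Raises ``ValueError`` if no line parses.
    """
    dialect = dialect or BlastDialect()
    path = Path(path)
    records: list[HitRecord] = []
    bad: list[tuple[int, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                query = fields[dialect.query_col]
                subject = fields[dialect.subject_col]
                bits = float(fields[dialect.bit_score_col])
                evalue = (
                    float(fields[dialect.e_value_col])
                    if dialect.e_value_col is not None
                    else None
                )
                records.append(HitRecord(query, subject, bits, evalue))
            except (IndexError, ValueError) as exc:
                bad.append((lineno, str(exc)))
    if not records:
        detail = "; ".join(f"line {n}: {m}" for n, m in bad[:5])
        raise ValueError(
            f"no parseable hit records in {path}"
            + (f" ({len(bad)} bad lines, e.g. {detail})" if bad else " (file empty)")
        )
    if bad:
        warnings.warn(
            f"{len(bad)} unparseable lines skipped in {path} "
            f"(first at line {bad[0][0]})",
            stacklevel=2,
        )
    return records


class GeneOrderMap:
    """Per-gene (species, contig, index) coordinates with O(1) neighborhood queries.

    Indices are 0-based contiguous ranks of genes along each contig, ordered
    by genomic start (ties broken by gene id).  Raw coordinates are discarded
    after indexing; strand is ignored.
    """

    def __init__(self, records: Iterable[tuple[str, str, str, float]]):
        """``records``: iterable of (gene_id, species_id, contig_id, start)."""
        by_contig: dict[tuple[str, str], list[tuple[float, str]]] = {}
        seen: set[str] = set()
        for gene, species, contig, start in records:
            if gene in seen:
                raise ValueError(f"duplicate gene id {gene!r} in gene-order input")
            seen.add(gene)
            by_contig.setdefault((species, contig), []).append((start, gene))
        self._coords: dict[str, tuple[str, str, int]] = {}
        self._contigs: dict[tuple[str, str], list[str]] = {}
        for key in sorted(by_contig):
            ordered = [g for _, g in sorted(by_contig[key], key=lambda t: (t[0], t[1]))]
            self._contigs[key] = ordered
            species, contig = key
            for idx, gene in enumerate(ordered):
                self._coords[gene] = (species, contig, idx)

    def __contains__(self, gene: str) -> bool:
        return gene in self._coords

    def __len__(self) -> int:
        return len(self._coords)

    @property
    def genes(self) -> list[str]:
        return sorted(self._coords)

    def coords(self, gene: str) -> tuple[str, str, int]:
        """(species, contig, index) of ``gene``; raises KeyError if unknown."""
        return self._coords[gene]

    def species_of(self, gene: str) -> str:
        return self._coords[gene][0]

    def contig_genes(self, species: str, contig: str) -> list[str]:
        return list(self._contigs[(species, contig)])

    def neighborhood(self, gene: str, k: int) -> list[str]:
        """Up to 2k genes with index distance in [1, k] on the gene's contig.

        Excludes the gene itself; truncated at contig ends.  ``k=0`` gives an
        empty list.
        """
        if gene not in self._coords:
            raise KeyError(f"unknown gene {gene!r}")
        species, contig, idx = self._coords[gene]
        row = self._contigs[(species, contig)]
        lo = max(0, idx - k)
        return row[lo:idx] + row[idx + 1 : idx + 1 + k]


def read_gene_order(path: str | Path) -> GeneOrderMap:
    """Read a gene-order TSV with columns gene_id, species_id, contig_id, start.

    A header row is detected (and skipped) when the fourth column of the
    first line is not numeric.
    """
    path = Path(path)
    rows: list[tuple[str, str, str, float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            try:
                start = float(fields[3])
            except ValueError:
                if lineno == 1 or not rows:
                    continue  # header row
                raise ValueError(f"{path}:{lineno}: unparseable start {fields[3]!r}")
            rows.append((fields[0], fields[1], fields[2], start))
    return GeneOrderMap(rows)


def read_gene_order_gff3(
    path: str | Path, species_id: str, feature_type: str = "gene"
) -> GeneOrderMap:
    """Build a GeneOrderMap from the gene features of a GFF3 file.

    GFF3 carries no species field, so ``species_id`` labels every record.
    One record is kept per gene (the feature's ID attribute).
    """
    import gffutils  # deferred: sqlite-backed, only needed for GFF input

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = [
        (feat.id, species_id, feat.seqid, float(feat.start))
        for feat in db.features_of_type(feature_type)
    ]
    if not rows:
        raise ValueError(f"no {feature_type!r} features found in {path}")
    return GeneOrderMap(rows)


class FamilyPartition:
    """Disjoint assignment of genes to families.

    Every gene carries exactly one label; the union of the families is the
    gene universe of the partition.
    """

    def __init__(self, assignment: Mapping[str, str]):
        self._assignment = dict(assignment)
        fams: dict[str, set[str]] = {}
        for gene, label in self._assignment.items():
            fams.setdefault(label, set()).add(gene)
        self._families = {label: frozenset(members) for label, members in fams.items()}

    @classmethod
    def from_clusters(cls, clusters: Iterable[Iterable[str]]) -> "FamilyPartition":
        """Build a partition from member sets, labelling families F000001,
        F000002, ... in lexicographic order of their smallest member."""
        sets = [sorted(set(c)) for c in clusters if c]
        sets.sort(key=lambda members: members[0])
        assignment: dict[str, str] = {}
        for i, members in enumerate(sets, start=1):
            label = f"F{i:06d}"
            for gene in members:
                if gene in assignment:
                    raise ValueError(f"gene {gene!r} appears in two clusters")
                assignment[gene] = label
        return cls(assignment)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self._assignment)

    @property
    def families(self) -> dict[str, frozenset[str]]:
        return dict(self._families)

    @property
    def n_families(self) -> int:
        return len(self._families)

    def __len__(self) -> int:
        return len(self._assignment)

    def __contains__(self, gene: str) -> bool:
        return gene in self._assignment

    def family_of(self, gene: str) -> str:
        return self._assignment[gene]

    def members(self, label: str) -> frozenset[str]:
        return self._families[label]

    def items(self):
        return self._assignment.items()

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, FamilyPartition)
            and self._assignment == other._assignment
        )

    def __hash__(self):  # partitions are mutable-free; hash by grouping
        return hash(frozenset(self._families.values()))

    def same_clustering(self, other: "FamilyPartition") -> bool:
        """True when both partitions group genes identically, labels aside."""
        return set(self._families.values()) == set(other._families.values())

    def restricted_to(self, genes: Iterable[str]) -> "FamilyPartition":
        keep = set(genes)
        return FamilyPartition(
            {g: lab for g, lab in self._assignment.items() if g in keep}
        )


def read_family_table(path: str | Path) -> FamilyPartition:
    """Read a TSV of gene_id -> family label.  A gene with two distinct
    labels is fatal; an empty file yields an empty partition with a warning."""
    path = Path(path)
    assignment: dict[str, str] = {}
    first_data = True
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            gene, label = fields[0], fields[1]
            if first_data:
                first_data = False
                if gene == "gene_id":
                    continue  # header row
            if gene in assignment and assignment[gene] != label:
                raise ValueError(
                    f"{path}:{lineno}: gene {gene!r} assigned to both "
                    f"{assignment[gene]!r} and {label!r}"
                )
            assignment[gene] = label
    if not assignment:
        warnings.warn(f"empty family table {path}", stacklevel=2)
    return FamilyPartition(assignment)


def _write_header(fh, columns: Sequence[str], params: Mapping | None) -> None:
    if params:
        for key in sorted(params):
            fh.write(f"# {key} = {params[key]}\n")
    fh.write("\t".join(columns) + "\n")


def write_clusters(
    partition: FamilyPartition, path: str | Path, params: Mapping | None = None
) -> None:
    """Write a partition as a gene_id/family TSV with a commented header."""
    with Path(path).open("w") as fh:
        _write_header(fh, ("gene_id", "family"), params)
        for gene in sorted(partition.genes):
            fh.write(f"{gene}\t{partition.family_of(gene)}\n")


def write_homolog_pairs(graph, path: str | Path, params: Mapping | None = None) -> None:
    """Write per-pair NC, SyS, SyC, decision value h and the homolog call.

    Scores are printed to 6 decimals; rows are ordered lexicographically.
    ``graph`` is a :class:`~genfamclust.decision.HomologyGraph`.
    """
    with Path(path).open("w") as fh:
        _write_header(fh, ("gene1", "gene2", "nc", "sys", "syc", "h", "call"), params)
        for (g1, g2), rec in sorted(graph.items()):
            fh.write(
                f"{g1}\t{g2}\t{rec.nc:.6f}\t{rec.sys:.6f}\t{rec.syc:.6f}"
                f"\t{rec.h:.6f}\t{int(rec.call)}\n"
            )


def read_homolog_pairs(path: str | Path):
    """Read a homolog-pair table back into a HomologyGraph."""
    from .decision import HomologyGraph, PairCall

    records: dict[tuple[str, str], PairCall] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("gene1\t"):
                continue
            g1, g2, nc, sys_, syc, h, call = line.split("\t")
            pair = (g1, g2) if g1 <= g2 else (g2, g1)
            records[pair] = PairCall(
                nc=float(nc), sys=float(sys_), syc=float(syc),
                h=float(h), call=bool(int(call)),
            )
    return HomologyGraph(records)


def write_nc_table(graph, path: str | Path, params: Mapping | None = None) -> None:
    """Write an NCGraph as gene1/gene2/nc TSV (6 decimals, sorted rows)."""
    with Path(path).open("w") as fh:
        _write_header(fh, ("gene1", "gene2", "nc"), params)
        for g1, g2, v in sorted(graph.edges()):
            fh.write(f"{g1}\t{g2}\t{v:.6f}\n")


def read_nc_table(path: str | Path):
    from .nc import NCGraph

    graph = NCGraph()
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("gene1\t"):
                continue
            g1, g2, v = line.split("\t")
            graph.add(g1, g2, float(v))
    return graph


def write_synteny_table(graph, path: str | Path, params: Mapping | None = None) -> None:
    """Write a SyntenyGraph as gene1/gene2/nc/sys/syc/h_size TSV."""
    with Path(path).open("w") as fh:
        _write_header(fh, ("gene1", "gene2", "nc", "sys", "syc", "h_size"), params)
        for (g1, g2), rec in sorted(graph.items()):
            fh.write(
                f"{g1}\t{g2}\t{rec.nc:.6f}\t{rec.sys:.6f}\t{rec.syc:.6f}"
                f"\t{rec.h_size}\n"
            )


def read_synteny_table(path: str | Path):
    from .synteny import PairSynteny, SyntenyGraph

    records: dict[tuple[str, str], PairSynteny] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("gene1\t"):
                continue
            g1, g2, nc, sys_, syc, h_size = line.split("\t")
            pair = (g1, g2) if g1 <= g2 else (g2, g1)
            records[pair] = PairSynteny(
                nc=float(nc), sys=float(sys_), syc=float(syc), h_size=int(h_size)
            )
    return SyntenyGraph(records)
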