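"""End-to-end pipeline: hits -> NC -> synteny -> decision -> clustering -> report.

Each stage writes its TSV output and the next stage consumes the written
file, so results are identical whether a stage was freshly computed or
skipped.  Stage skipping is checksum-based: a stage reruns only when its
input files or parameters changed.  A stage that fails leaves its partial
output behind with a ``.partial`` suffix.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import clustering, decision, evaluation, io, nc, synteny

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    hits: str
    gene_order: str
    outdir: str
    gold: str | None = None
    query_species: list[str] = field(default_factory=list)
    nc_min: float = nc.DEFAULT_NC_MIN
    k: int = 5
    beta: float = 0.3
    syc_weight: float = 0.25
    intercept: float = 0.25
    method: str = "single"
    tau: float = 0.5
    weight_source: str = "gfc"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("hits", "gene_order"):
            path = getattr(self, name)
            if not Path(path).is_file():
                raise FileNotFoundError(f"{name} file not found: {path}")
        if self.gold and not Path(self.gold).is_file():
            raise FileNotFoundError(f"gold file not found: {self.gold}")
        synteny.SyntenyParams(k=self.k, beta=self.beta)
        clustering.LinkageConfig(
            method=self.method, tau=self.tau, weight_source=self.weight_source
        )

    def header(self) -> dict:
        d = asdict(self)
        d["query_species"] = ",".join(self.query_species)
        return d


def load_config(path: str | Path) -> PipelineConfig:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def _digest(*parts: str | bytes) -> str:
    h = hashlib.sha256()
    for part in parts:
        h.update(part.encode() if isinstance(part, str) else part)
        h.update(b"\x00")
    return h.hexdigest()


def _file_digest(path: str | Path) -> str:
    return _digest(Path(path).read_bytes())


class _Stages:
    """Tracks per-stage input/parameter checksums in a manifest file."""

    def __init__(self, outdir: Path):
        self.path = outdir / "manifest.json"
        self.manifest: dict[str, str] = {}
        if self.path.is_file():
            self.manifest = json.loads(self.path.read_text())
        self.updated: dict[str, str] = {}

    def fresh(self, stage: str, signature: str, outputs: list[Path]) -> bool:
        self.updated[stage] = signature
        return self.manifest.get(stage) == signature and all(
            p.is_file() for p in outputs
        )

    def save(self) -> None:
        self.path.write_text(json.dumps(self.updated, indent=1, sort_keys=True))


def _writing(path: Path):
    """Context: write to .partial, rename into place only on success."""

    class _Ctx:
        def __enter__(self):
            self.tmp = path.with_suffix(path.suffix + ".partial")
            return self.tmp

        def __exit__(self, exc_type, exc, tb):
            if exc_type is None:
                self.tmp.replace(path)
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run all stages; returns the paths of the artifacts produced."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = _Stages(outdir)
    header = config.header()

    paths = {
        "nc": outdir / "nc.tsv",
        "syc": outdir / "syc.tsv",
        "homologs": outdir / "homologs.tsv",
        "families": outdir / "families.tsv",
    }
    if config.gold:
        paths["report"] = outdir / "report.tsv"

    hits_sig = _file_digest(config.hits)
    order_sig = _file_digest(config.gene_order)

    # stage 1: NC from raw hits
    sig = _digest("nc", hits_sig, str(config.nc_min), ",".join(sorted(config.query_species)))
    if not stages.fresh("nc", sig, [paths["nc"]]):
        logger.info("stage nc: computing")
        hits = io.read_blast_tabular(config.hits)
        table = nc.normalize_scores(hits)
        candidates = None
        if config.query_species:
            order = io.read_gene_order(config.gene_order)
            qset = set(config.query_species)
            candidates = [
                (g1, g2)
                for g1, g2 in table.pairs()
                if g1 in order and g2 in order
                and order.species_of(g1) in qset and order.species_of(g2) in qset
            ]
        graph = nc.nc_all(table, candidate_pairs=candidates, nc_min=config.nc_min)
        with _writing(paths["nc"]) as tmp:
            io.write_nc_table(graph, tmp, params=header)
        logger.info("stage nc: %d edges retained", len(graph))
    else:
        logger.info("stage nc: up to date, skipping")

    # stage 2: synteny scores for NC edges above beta
    nc_sig = _file_digest(paths["nc"])
    sig = _digest("synteny", nc_sig, order_sig, str(config.k), str(config.beta))
    if not stages.fresh("synteny", sig, [paths["syc"]]):
        logger.info("stage synteny: computing")
        graph = io.read_nc_table(paths["nc"])
        order = io.read_gene_order(config.gene_order)
        params = synteny.SyntenyParams(k=config.k, beta=config.beta)
        syn = synteny.synteny_all(graph, order, params)
        with _writing(paths["syc"]) as tmp:
            io.write_synteny_table(syn, tmp, params=header)
        logger.info("stage synteny: %d candidate pairs scored", len(syn))
    else:
        logger.info("stage synteny: up to date, skipping")

    # stage 3: decision boundary
    syc_sig = _file_digest(paths["syc"])
    sig = _digest("infer", syc_sig, str(config.syc_weight), str(config.intercept))
    if not stages.fresh("infer", sig, [paths["homologs"]]):
        logger.info("stage infer: computing")
        syn = io.read_synteny_table(paths["syc"])
        dparams = decision.DecisionParams(
            syc_weight=config.syc_weight, intercept=config.intercept
        )
        hom = decision.infer_homologs(syn, dparams)
        with _writing(paths["homologs"]) as tmp:
            io.write_homolog_pairs(hom, tmp, params=header)
        logger.info("stage infer: %d of %d pairs called", hom.n_called, len(hom))
    else:
        logger.info("stage infer: up to date, skipping")

    # stage 4: clustering into families
    hom_sig = _file_digest(paths["homologs"])
    sig = _digest(
        "cluster", hom_sig, order_sig, config.method, str(config.tau), config.weight_source
    )
    if not stages.fresh("cluster", sig, [paths["families"]]):
        logger.info("stage cluster: computing")
        hom = io.read_homolog_pairs(paths["homologs"])
        order = io.read_gene_order(config.gene_order)
        edges = clustering.homologs_to_graph(hom, config.weight_source)
        cfg = clustering.LinkageConfig(
            method=config.method, tau=config.tau, weight_source=config.weight_source
        )
        partition = clustering.cluster(edges, cfg, order.genes)
        with _writing(paths["families"]) as tmp:
            io.write_clusters(partition, tmp, params=header)
        logger.info("stage cluster: %d families", partition.n_families)
    else:
        logger.info("stage cluster: up to date, skipping")

    # stage 5: evaluation against a gold standard, when provided
    if config.gold:
        fam_sig = _file_digest(paths["families"])
        sig = _digest("evaluate", fam_sig, _file_digest(config.gold))
        if not stages.fresh("evaluate", sig, [paths["report"]]):
            logger.info("stage evaluate: computing")
            partition = io.read_family_table(paths["families"])
            gold = io.read_family_table(config.gold)
            quality = evaluation.partition_quality(partition, gold)
            precision, recall = evaluation.pairwise_pr(partition, gold)
            mi = evaluation.mutual_information(
                evaluation.PairLabeling(partition), evaluation.PairLabeling(gold)
            )
            jac = evaluation.jaccard(
                evaluation.intra_family_pairs(partition),
                evaluation.intra_family_pairs(gold),
            )
            with _writing(paths["report"]) as tmp:
                with Path(tmp).open("w") as fh:
                    for key in sorted(header):
                        fh.write(f"# {key} = {header[key]}\n")
                    fh.write("metric\tvalue\n")
                    fh.write(f"quality_weighted\t{quality.weighted:.6f}\n")
                    fh.write(f"quality_unweighted\t{quality.unweighted:.6f}\n")
                    fh.write(f"pairwise_precision\t{precision:.6f}\n")
                    fh.write(f"pairwise_recall\t{recall:.6f}\n")
                    fh.write(f"mutual_information\t{mi:.6f}\n")
                    fh.write(f"jaccard\t{jac:.6f}\n")
        else:
            logger.info("stage evaluate: up to date, skipping")

    stages.save()
    return paths
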