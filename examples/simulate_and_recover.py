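"""Round trip: simulate a genome history, run the pipeline, recover families.

Evolution is frozen (no duplication, loss, translocation or sequence decay),
so the pipeline must reconstruct the true gene families exactly.
"""

import tempfile
from pathlib import Path

from genfamclust import (
    PipelineConfig,
    SimulationParams,
    export,
    read_family_table,
    run_pipeline,
    simulate,
)

params = SimulationParams(
    n_ancestral_genes=15,
    dup_rate=0.0,
    loss_rate=0.0,
    translocation_rate=0.0,
    divergence_rate=0.0,
    noise_sigma=0.0,
    seed=6,
)
truth = simulate(params)
print(f"simulated {len(truth.families.genes)} genes in "
      f"{truth.families.n_families} true families over 6 species")

with tempfile.TemporaryDirectory() as tmp:
    data = export(truth, Path(tmp) / "data")
    config = PipelineConfig(
        hits=str(data["hits"]),
        gene_order=str(data["gene_order"]),
        gold=str(data["gold"]),
        outdir=str(Path(tmp) / "out"),
        tau=0.5,
    )
    artifacts = run_pipeline(config)
    recovered = read_family_table(artifacts["families"])
    exact = recovered.same_clustering(truth.families)
    print(f"pipeline recovered {recovered.n_families} families; "
          f"exact match with the ground truth: {exact}")
    print("report written by the pipeline:")
    for line in artifacts["report"].read_text().splitlines():
        if not line.startswith("#"):
            print(" ", line)
print("quality 1.0 and precision/recall 1.0 mean every family was recovered intact.")
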