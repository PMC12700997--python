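"""Config-driven pipeline orchestration with deterministic run manifests.

Stages run in dependency order (simulate → stats/screens); every
stochastic stage consumes exactly one child seed derived from the root
seed via ``numpy.random.SeedSequence([root_seed, stage_index])``, so a
config plus seed fully determines every output byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import io as cio
from .convergent import co_loss_screen, discover_focal_sets
from .lifecycle import (
    asymmetry_histogram,
    constriction_summary,
    generation_time_histogram,
    pair_asymmetry,
)
from .phototrophy import detect_gene_cluster, screen_genomes
from .synthetic import (
    DimorphicParams,
    PlantedLossSpec,
    PlantedPGCSpec,
    simulate_annotated_genomes,
    simulate_lineage,
    simulate_loss_matrix,
)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "STAGES"]

log = logging.getLogger("caulotraits")

STAGES = (
    "simulate_lineage",
    "simulate_matrix",
    "simulate_genomes",
    "asymmetry",
    "convergent_loss",
    "phototrophy",
)


@dataclass
class RunConfig:
    stages: list[str]
    out_dir: Path
    seed: int = 0
    params: dict[str, dict] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        cfg = cls(
            stages=list(raw.get("stages", STAGES)),
            out_dir=Path(raw.get("out_dir", "caulotraits_run")),
            seed=int(raw.get("seed", 0)),
            params=dict(raw.get("params", {})),
            inputs={k: str(v) for k, v in raw.get("inputs", {}).items()},
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for name, path in self.inputs.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"input {name!r}: {path} does not exist")

    def canonical(self) -> str:
        payload = {
            "stages": self.stages,
            "seed": self.seed,
            "params": self.params,
            "inputs": self.inputs,
        }
        return json.dumps(payload, sort_keys=True)


@dataclass
class RunManifest:
    tool_version: str
    config_hash: str
    seed: int
    stage_seeds: dict[str, int]
    input_checksums: dict[str, str]
    outputs: dict[str, str]  # path -> sha256
    row_counts: dict[str, int]
    timings_s: dict[str, float]

    def write(self, path: str | Path) -> None:
        with cio.atomic_write(path) as tmp:
            tmp.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def stage_seed(root_seed: int, stage: str) -> int:
    """Documented, stable child-seed derivation (stage index keyed)."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([root_seed, idx]).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the selected stages and write a deterministic manifest."""
    from . import __version__

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: stage_seed(config.seed, s) for s in config.stages}
    outputs: dict[str, str] = {}
    rows: dict[str, int] = {}
    timings: dict[str, float] = {}

    def emit(name: str, writer, obj, count: int) -> Path:
        path = out / name
        writer(obj, path)
        outputs[name] = cio.sha256_file(path)
        rows[name] = count
        return path

    ordered = [s for s in STAGES if s in config.stages]
    state: dict[str, Any] = {}
    for stage in ordered:
        t0 = time.perf_counter()
        p = config.params.get(stage, {})
        log.info("stage %s (seed %d)", stage, seeds[stage])
        try:
            if stage == "simulate_lineage":
                table = simulate_lineage(DimorphicParams(**{**p, "seed": seeds[stage]}))
                state["lineage"] = table
                emit("lineage.tsv", cio.write_lineage, table, len(table))
            elif stage == "simulate_matrix":
                spec = PlantedLossSpec(**{**p, "seed": seeds[stage]})
                tree, matrix, truth = simulate_loss_matrix(None, spec)
                state.update(tree=tree, matrix=matrix, truth=truth)
                emit("tree.nwk", cio.write_newick, tree, len(tree.tips))
                emit("matrix.tsv", cio.write_matrix, matrix, len(matrix.genome_ids))
            elif stage == "simulate_genomes":
                spec = PlantedPGCSpec(**{**p, "seed": seeds[stage]})
                annotations, truths = simulate_annotated_genomes(spec)
                state["annotations"] = annotations
                emit(
                    "annotations.tsv",
                    cio.write_annotations,
                    annotations,
                    sum(len(a.genes) for a in annotations),
                )
            elif stage == "asymmetry":
                table = state.get("lineage")
                if table is None:
                    table = cio.read_lineage(config.inputs["lineage"])
                records, exclusions = pair_asymmetry(table)
                hist = asymmetry_histogram(records, **p.get("histogram", {}))
                gen_hist = generation_time_histogram(table, **p.get("generation", {}))
                chist, midcell, sym_p = constriction_summary(
                    table, seed=seeds[stage], **p.get("constriction", {})
                )
                import pandas as pd

                rec_df = pd.DataFrame(
                    {
                        "mother_id": [r.mother_id for r in records],
                        "t1": [r.t1 for r in records],
                        "t2": [r.t2 for r in records],
                        "delta_t": [r.delta_t for r in records],
                        "degree": [r.degree for r in records],
                    }
                )

                def wtsv(df, path):
                    with cio.atomic_write(path) as tmp:
                        df.to_csv(tmp, sep="\t", index=False, float_format="%.6g")

                emit("asymmetry_records.tsv", wtsv, rec_df, len(rec_df))
                emit("asymmetry_hist.tsv", wtsv, hist.to_frame(), len(hist.counts))
                emit("generation_hist.tsv", wtsv, gen_hist.to_frame(), len(gen_hist.counts))
                summary = {
                    "n_pairs": len(records),
                    "exclusions": exclusions,
                    "midcell_fraction": midcell,
                    "symmetry_p": sym_p,
                }

                def wjson(obj, path):
                    with cio.atomic_write(path) as tmp:
                        tmp.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")

                emit("asymmetry_summary.json", wjson, summary, len(records))
            elif stage == "convergent_loss":
                tree = state.get("tree") or cio.read_newick(config.inputs["tree"])
                matrix = state.get("matrix") or cio.read_matrix(config.inputs["matrix"])
                markers = p.get("marker_families")
                if markers:
                    focal = discover_focal_sets(matrix, tree, markers)
                elif state.get("truth") is not None:
                    below = tree.clade_map()
                    focal = [below[s] for s in sorted(state["truth"].focal_lineages)]
                else:
                    raise ValueError("convergent_loss needs marker_families or a simulated truth")
                module = co_loss_screen(
                    matrix, tree, focal, conservation_min=p.get("conservation_min", 0.75)
                )

                def wtsv(df, path):
                    with cio.atomic_write(path) as tmp:
                        df.to_csv(tmp, sep="\t", index=False, float_format="%.6g")

                emit("convergent_module.tsv", wtsv, module.report(), len(module.family_ids))
                state["module"] = module
            elif stage == "phototrophy":
                annotations = state.get("annotations")
                if annotations is None:
                    annotations = cio.read_annotations(config.inputs["annotations"])
                table, frac = screen_genomes(annotations)
                cluster_rows = []
                from .phototrophy import CBB_CLUSTER_GENES, PGC_CORE_ORDER

                category = {f for f, _ in PGC_CORE_ORDER} | {f for f, _ in CBB_CLUSTER_GENES}
                for ann in annotations:
                    for region in detect_gene_cluster(ann, category, **p.get("cluster", {})):
                        cluster_rows.append(
                            {
                                "genome_id": ann.genome_id,
                                "contig_id": region.contig_id,
                                "first_index": region.first_index,
                                "last_index": region.last_index,
                                "families": ",".join(region.families),
                                "left_at_contig_end": int(region.left_at_contig_end),
                                "right_at_contig_end": int(region.right_at_contig_end),
                            }
                        )
                import pandas as pd

                def wtsv(df, path):
                    with cio.atomic_write(path) as tmp:
                        df.to_csv(tmp, sep="\t", index=False, float_format="%.6g")

                emit("phototrophy_calls.tsv", wtsv, table, len(table))
                emit("pgc_clusters.tsv", wtsv, pd.DataFrame(cluster_rows), len(cluster_rows))
        except Exception:
            log.error("stage %s failed; partial outputs kept in %s", stage, out)
            raise
        timings[stage] = time.perf_counter() - t0

    manifest = RunManifest(
        tool_version=__version__,
        config_hash=hashlib.sha256(config.canonical().encode()).hexdigest(),
        seed=config.seed,
        stage_seeds=seeds,
        input_checksums={k: cio.sha256_file(v) for k, v in config.inputs.items()},
        outputs=outputs,
        row_counts=rows,
        timings_s=timings,
    )
    manifest.write(out / "manifest.json")
    return manifest
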