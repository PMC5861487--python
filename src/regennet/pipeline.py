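"""End-to-end orchestration: preprocess -> candidate -> infer -> compare.

A run is described by a single YAML config (every CLI flag overrides it),
executed deterministically, and summarized in a JSON manifest recording the
package version, a hash of the config, and per-stage input/output counts.
A stage failure aborts the run with the stage name and removes that run's
partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .candidate import map_orthologs, restrict_to_pool
from .compare import compare_networks, write_comparison, ComparisonResult
from .dynamics import InferenceConfig, infer_network
from .errors import PipelineError
from .io_formats import (
    TimeDesign,
    read_expression_table,
    read_ortholog_map,
    read_ppi_edges,
    write_network,
)
from .preprocess import anova_filter, log2_transform, percentile_normalize

logger = logging.getLogger(__name__)


def design_from_dict(d: Mapping) -> TimeDesign:
    """Build a TimeDesign from {time_points: [...], replicates: int | [...]}."""
    tp = tuple(float(t) for t in d["time_points"])
    reps = d["replicates"]
    if isinstance(reps, int):
        reps = (reps,) * len(tp)
    return TimeDesign(tp, tuple(int(r) for r in reps))


def load_design(path: str | Path) -> TimeDesign:
    with open(path, encoding="utf-8") as fh:
        return design_from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class RunConfig:
    """Validated parameters of a full pipeline run."""

    conditions: dict[str, str]  # name -> expression TSV path
    design: TimeDesign
    human_ppi: str
    orthologs: str
    out_dir: str
    ppi_dialect: str = "simple_tsv"
    alpha: float = 0.05
    percentile: float | None = 75.0
    log2: bool = False
    m_points: int | str = "auto"
    merge: str = "union"
    top_k: int = 10

    def __post_init__(self) -> None:
        if len(self.conditions) < 1:
            raise ValueError("at least one condition is required")
        InferenceConfig(m_points=self.m_points, merge=self.merge)  # validates

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        design = design_from_dict(raw.pop("design"))
        return cls(design=design, **raw)

    def to_dict(self) -> dict:
        return {
            "conditions": dict(self.conditions),
            "design": {
                "time_points": list(self.design.time_points),
                "replicates": list(self.design.replicates),
            },
            "human_ppi": self.human_ppi,
            "orthologs": self.orthologs,
            "out_dir": self.out_dir,
            "ppi_dialect": self.ppi_dialect,
            "alpha": self.alpha,
            "percentile": self.percentile,
            "log2": self.log2,
            "m_points": self.m_points,
            "merge": self.merge,
            "top_k": self.top_k,
        }


def run_pipeline(config: RunConfig):
    """Execute all stages; returns (ComparisonResult or None, manifest dict).

    The comparison stage needs >= 2 conditions and is skipped (with a log
    line) for single-condition runs.  Outputs per condition: pool_<name>.tsv,
    candidate_<name>.tsv, refined_<name>.tsv; plus compare/ and manifest.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    manifest: dict = {
        "regennet_version": __version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
    }

    def fail(stage: str, exc: Exception):
        for p in created:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, str(exc)) from exc

    # --- shared inputs -----------------------------------------------------
    try:
        human = read_ppi_edges(config.human_ppi, dialect=config.ppi_dialect)
        orthologs = read_ortholog_map(config.orthologs)
        projected = map_orthologs(human, orthologs)
        manifest["stages"]["project"] = {
            "human_edges": len(human),
            "ortholog_pairs": len(orthologs),
            "projected_edges": len(projected),
        }
        logger.info(
            "project: %d human edges x %d ortholog pairs -> %d zebrafish edges",
            len(human), len(orthologs), len(projected),
        )
    except PipelineError:
        raise
    except Exception as exc:
        fail("project", exc)

    refined_nets = {}
    infer_cfg = InferenceConfig(m_points=config.m_points, merge=config.merge)
    for name, expr_path in config.conditions.items():
        # --- preprocess ----------------------------------------------------
        try:
            matrix = read_expression_table(expr_path, config.design, condition_label=name)
            if config.percentile is not None:
                matrix = percentile_normalize(matrix, config.percentile)
            if config.log2:
                matrix = log2_transform(matrix)
            pool = anova_filter(matrix, alpha=config.alpha)
            pool_path = out / f"pool_{name}.tsv"
            pool.to_frame().to_csv(pool_path, sep="\t", index=False)
            created.append(pool_path)
            manifest["stages"][f"preprocess_{name}"] = {
                "proteins": matrix.n_proteins,
                "pool_size": len(pool),
            }
            logger.info("preprocess[%s]: %d proteins -> pool of %d", name, matrix.n_proteins, len(pool))
        except Exception as exc:
            fail(f"preprocess:{name}", exc)

        # --- candidate -----------------------------------------------------
        try:
            cand = restrict_to_pool(projected, pool)
            cand_path = out / f"candidate_{name}.tsv"
            write_network(cand, cand_path)
            created.append(cand_path)
            manifest["stages"][f"candidate_{name}"] = {
                "nodes": len(cand.nodes),
                "edges": cand.n_edges,
            }
            logger.info("candidate[%s]: %d nodes, %d edges", name, len(cand.nodes), cand.n_edges)
        except Exception as exc:
            fail(f"candidate:{name}", exc)

        # --- infer ---------------------------------------------------------
        try:
            refined = infer_network(cand, matrix, infer_cfg)
            refined_path = out / f"refined_{name}.tsv"
            write_network(refined, refined_path)
            created.append(refined_path)
            refined_nets[name] = refined
            manifest["stages"][f"infer_{name}"] = {
                "nodes": len(refined.nodes),
                "edges": refined.n_edges,
            }
            logger.info("infer[%s]: %d nodes, %d edges retained", name, len(refined.nodes), refined.n_edges)
        except Exception as exc:
            fail(f"infer:{name}", exc)

    # --- compare -----------------------------------------------------------
    result = None
    if len(refined_nets) >= 2:
        try:
            result = compare_networks(refined_nets, top_k=config.top_k)
            write_comparison(result, out / "compare")
            manifest["stages"]["compare"] = result.counts()
            logger.info("compare: %d core proteins", len(result.core_proteins))
        except Exception as exc:
            fail("compare", exc)
    else:
        logger.info("single condition: comparison stage skipped")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return result, manifest
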