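"""End-to-end orchestration: screen -> enrich -> stratify, with a manifest.

A run is driven by a flat key=value configuration file (see
:func:`load_config`); every stochastic stage draws its seed from one root
seed split by stage name, so runs are reproducible and stable under stage
reordering. On any stage error, partial outputs are removed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .enrichment import enrich
from .io import read_cohort, read_expression, read_gmt, write_table
from .screen import ScreenParams, screen_genes
from .survival import ScoreSpec, stratified_survival

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "stage_seed"]


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, keyed by stage name."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclasses.dataclass
class PipelineConfig:
    expression: Path
    expression_format: str
    gmt: Path
    cohort: Path
    out_dir: Path
    anchor: str
    score_genes: tuple[str, ...]
    score_weights: tuple[float, ...] | None = None
    control_gene: str | None = None
    transform: str = "log2p1"
    fraction: float = 0.2
    n_permutations: int = 999
    alpha: float = 0.05
    dcor_variant: str = "standard"
    min_nonzero_fraction: float = 0.05
    expression_scale: str = "counts"
    seed: int = 0

    def __post_init__(self) -> None:
        self.expression = Path(self.expression)
        self.gmt = Path(self.gmt)
        self.cohort = Path(self.cohort)
        self.out_dir = Path(self.out_dir)
        for path in (self.expression, self.gmt, self.cohort):
            if not path.exists():
                raise FileNotFoundError(f"configured input does not exist: {path}")


_BOOLISH = {"true": True, "false": False}


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a flat key=value config file (one pair per line, # comments)."""
    raw: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {lineno}: expected key=value")
        key, value = line.split("=", 1)
        raw[key.strip()] = value.strip()

    def take(key: str, default=None, cast=str):
        if key not in raw:
            if default is None and key not in ("control_gene", "score_weights"):
                raise KeyError(f"{path}: missing required config key {key!r}")
            return default
        return cast(raw.pop(key))

    cfg = PipelineConfig(
        expression=take("expression"),
        expression_format=take("expression_format", "tsv"),
        gmt=take("gmt"),
        cohort=take("cohort"),
        out_dir=take("out_dir"),
        anchor=take("anchor"),
        score_genes=tuple(take("score_genes").split(",")),
        score_weights=(
            tuple(float(w) for w in raw.pop("score_weights").split(","))
            if "score_weights" in raw
            else None
        ),
        control_gene=raw.pop("control_gene", None),
        transform=take("transform", "log2p1"),
        fraction=take("fraction", 0.2, float),
        n_permutations=take("n_permutations", 999, int),
        alpha=take("alpha", 0.05, float),
        dcor_variant=take("dcor_variant", "standard"),
        min_nonzero_fraction=take("min_nonzero_fraction", 0.05, float),
        expression_scale=take("expression_scale", "counts"),
        seed=take("seed", 0, int),
    )
    if raw:
        raise ValueError(f"{path}: unknown config keys {sorted(raw)}")
    return cfg


def _score_specs(config: PipelineConfig) -> dict[str, ScoreSpec]:
    """Single-gene, pair, and optional control-pair score specifications."""
    specs: dict[str, ScoreSpec] = {}
    for gene in config.score_genes:
        specs[gene] = ScoreSpec(genes=(gene,), transform=config.transform)
    if len(config.score_genes) == 2:
        specs["+".join(config.score_genes)] = ScoreSpec(
            genes=config.score_genes,
            weights=config.score_weights,
            transform=config.transform,
        )
    if config.control_gene:
        specs[config.control_gene] = ScoreSpec(
            genes=(config.control_gene,), transform=config.transform
        )
        specs[f"{config.anchor}+{config.control_gene}"] = ScoreSpec(
            genes=(config.anchor, config.control_gene), transform=config.transform
        )
    return specs


def run_pipeline(config: PipelineConfig) -> dict:
    """Run screen -> enrichment -> survival stratification; return the manifest."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {
        "version": __version__,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": {},
    }

    def emit(name: str, table) -> Path:
        out = config.out_dir / name
        write_table(table, out)
        written.append(out)
        return out

    stage = "load"
    try:
        t0 = time.perf_counter()
        matrix = read_expression(
            config.expression, config.expression_format, scale=config.expression_scale
        )
        gene_sets = read_gmt(config.gmt)
        cohort_genes = set(config.score_genes)
        if config.control_gene:
            cohort_genes |= {config.anchor, config.control_gene}
        cohort = read_cohort(config.cohort, sorted(cohort_genes))
        manifest["stages"]["load"] = {
            "n_genes": matrix.n_genes,
            "n_samples": matrix.n_samples,
            "n_gene_sets": len(gene_sets),
            "n_patients": cohort.n_patients,
            "seconds": round(time.perf_counter() - t0, 3),
        }

        stage = "screen"
        t0 = time.perf_counter()
        params = ScreenParams(
            anchor=config.anchor,
            n_permutations=config.n_permutations,
            alpha=config.alpha,
            dcor_variant=config.dcor_variant,
            min_nonzero_fraction=config.min_nonzero_fraction,
            seed=stage_seed(config.seed, "screen"),
        )
        records = screen_genes(matrix, params)
        emit("screen.tsv", records)
        intersection = [r.gene_id for r in records if r.in_intersection]
        universe = [r.gene_id for r in records]
        manifest["stages"]["screen"] = {
            "n_tested": len(records),
            "n_intersection": len(intersection),
            "seconds": round(time.perf_counter() - t0, 3),
        }
        logger.info("screen: %d genes tested, %d in intersection", len(records), len(intersection))

        stage = "enrich"
        t0 = time.perf_counter()
        if intersection:
            enr = enrich(intersection, gene_sets, universe)
            emit("enrichment.tsv", enr)
            top_terms = [r.term_id for r in enr[:5]]
        else:
            emit("enrichment.tsv", pd.DataFrame(columns=["term_id", "term_name", "p", "q"]))
            top_terms = []
        manifest["stages"]["enrich"] = {
            "n_terms_tested": len(enr) if intersection else 0,
            "top_terms": top_terms,
            "seconds": round(time.perf_counter() - t0, 3),
        }

        stage = "survival"
        t0 = time.perf_counter()
        surv_summary = {}
        for label, spec in _score_specs(config).items():
            res = stratified_survival(cohort, spec, config.fraction)
            safe = label.replace("+", "_")
            emit(f"survival_{safe}_long.tsv", res.long_table)
            emit(
                f"survival_{safe}_km_high.tsv",
                pd.DataFrame(
                    {
                        "time": res.km_high.event_times,
                        "survival": res.km_high.survival,
                        "at_risk": res.km_high.at_risk,
                    }
                ),
            )
            emit(
                f"survival_{safe}_km_low.tsv",
                pd.DataFrame(
                    {
                        "time": res.km_low.event_times,
                        "survival": res.km_low.survival,
                        "at_risk": res.km_low.at_risk,
                    }
                ),
            )
            surv_summary[label] = {
                "k": res.k,
                "chi2": res.logrank.chi2,
                "p": res.logrank.p,
            }
            logger.info("survival[%s]: chi2=%.3f p=%.4g", label, res.logrank.chi2, res.logrank.p)
        manifest["stages"]["survival"] = {
            "scores": surv_summary,
            "seconds": round(time.perf_counter() - t0, 3),
        }

        manifest["outputs"] = [str(p) for p in written]
        manifest_path = config.out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return manifest
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
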