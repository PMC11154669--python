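"""End-to-end orchestration: preprocess -> fit -> project -> associate -> query.

:class:`PipelineConfig` names the input files and hyper-parameters;
:func:`run_pipeline` chains the stages, writing every stage's outputs and a
run log under one output directory.  Re-running with the same config and seed
reproduces identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import io as pio
from .containers import RAW_COUNTS, TPM, ZSCORED
from .plier import PlierConfig, fit
from .preprocess import (
    build_prior_matrix,
    intersect_genes,
    log_transform,
    tpm_normalize,
    zscore_genes,
)
from .query import rank_studies
from .transfer import associate_lvs, project_study

log = logging.getLogger("plierlite")


@dataclass
class PipelineConfig:
    """Paths and parameters for a full pipeline run (JSON round-trippable)."""

    expression: str
    metadata: str
    gene_sets: str
    output_dir: str
    expression_state: str = ZSCORED        # raw_counts | tpm | zscored
    gene_lengths: str | None = None        # required when state is raw_counts
    hierarchy: str | None = None
    target_expression: str | None = None
    target_metadata: str | None = None
    target_state: str = ZSCORED
    min_genes: int = 5
    leaf_only: bool = True
    log_transform: bool = False
    plier: PlierConfig = field(default_factory=PlierConfig)
    fdr: float = 0.05
    top_n: int = 10
    top_genes_k: int = 20
    query_lv: str | None = None            # default: most significant LV
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.plier, dict):
            self.plier = PlierConfig(**self.plier)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def validate_paths(self) -> None:
        for name in ("expression", "metadata", "gene_sets", "gene_lengths",
                     "hierarchy", "target_expression", "target_metadata"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage=%s status=start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                log.error("stage=%s status=error cause=%r", name, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage=%s status=done seconds=%.2f", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage; returns a map of output names to written paths."""
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    outputs: dict[str, Path] = {"log": out / "run.log"}
    try:
        config.to_json(out / "config.json")
        outputs["config"] = out / "config.json"

        @_stage("preprocess")
        def _preprocess():
            expr = pio.read_expression(config.expression, state=config.expression_state)
            if expr.state == RAW_COUNTS:
                if config.gene_lengths is None:
                    raise ValueError("raw counts input requires a gene_lengths file")
                expr = tpm_normalize(expr, pio.read_gene_lengths(config.gene_lengths))
            if config.log_transform and expr.state in (RAW_COUNTS, TPM):
                expr = log_transform(expr)
            gene_sets = pio.read_gmt(config.gene_sets)
            hierarchy = pio.read_hierarchy(config.hierarchy) if config.hierarchy else None
            prior, dropped = build_prior_matrix(
                gene_sets,
                gene_universe=expr.gene_ids,
                hierarchy=hierarchy,
                min_genes=config.min_genes,
                leaf_only=config.leaf_only,
            )
            for name, reason in dropped.items():
                log.info("warning=dropped_set set=%s reason=%r", name, reason)
            expr, prior = intersect_genes(expr, prior)
            if expr.state != ZSCORED:
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    expr = zscore_genes(expr)
                for w in caught:
                    log.info("warning=constant_genes detail=%r", str(w.message))
            return expr, prior

        expr, prior = _preprocess()

        @_stage("train")
        def _train():
            model = fit(expr, prior, config.plier)
            pio.save_model(model, out / "model")
            return model

        model = _train()
        outputs["model"] = out / "model"

        association = None
        if config.target_expression:
            @_stage("project_associate")
            def _associate():
                target = pio.read_expression(config.target_expression, state=config.target_state)
                if target.state != ZSCORED:
                    target = zscore_genes(target)
                meta = pio.read_metadata(config.target_metadata)
                B_target = project_study(target, model)
                B_target.to_csv(out / "B_target.tsv", sep="\t", float_format=pio.FLOAT_FORMAT)
                table = associate_lvs(B_target, meta, fdr=config.fdr)
                table.to_csv(out / "association.tsv", sep="\t", index=False,
                             float_format=pio.FLOAT_FORMAT)
                return table

            association = _associate()
            outputs["association"] = out / "association.tsv"
            outputs["b_target"] = out / "B_target.tsv"

        @_stage("query")
        def _query():
            lv = config.query_lv
            if lv is None and association is not None and association["significant"].any():
                hits = association[association["significant"]]
                lv = hits.sort_values(["p_adj", "lv_id"]).iloc[0]["lv_id"]
            if lv is None:
                lv = model.lv_ids[0]
            meta = pio.read_metadata(config.metadata)
            ranking = rank_studies(
                model,
                meta.set_index("sample_id")["study_id"],
                lv,
                top_n=config.top_n,
            )
            ranking.to_frame().to_csv(out / "ranking.tsv", sep="\t", index=False,
                                      float_format=pio.FLOAT_FORMAT)
            labels = [
                {"study_id": e.study_id, "sample_id": s, "cluster": c}
                for e in ranking.entries
                for s, c in e.labels.items()
            ]
            import pandas as pd

            pd.DataFrame(labels).to_csv(out / "cluster_labels.tsv", sep="\t", index=False)
            for study, reason in ranking.excluded.items():
                log.info("warning=ineligible_study study=%s reason=%r", study, reason)
            return ranking

        _query()
        outputs["ranking"] = out / "ranking.tsv"
        outputs["cluster_labels"] = out / "cluster_labels.tsv"
        return outputs
    finally:
        log.removeHandler(handler)
        handler.close()
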