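"""End-to-end orchestration: align -> impute -> filter -> test -> correct -> call.

``run_huge`` executes the full discovery pipeline on file inputs and writes a
run directory with the LED table, per-group diagnostics, the
method-comparison table, a bipartite graph export and a manifest recording
every threshold actually applied.  Outputs are byte-stable given fixed
inputs and configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import stats_engine
from .core_data import (
    CohortSpec,
    align_samples,
    knn_impute,
    read_matrix,
)
from .essentiality_filter import (
    AML_PRESET,
    EssentialityFilterParams,
    select_essential_genes,
)
from .evaluation import compare_methods
from .led_calling import (
    EdgeList,
    LEDThresholds,
    call_leds,
    classify_leds,
    export_bipartite_graph,
    relation_filter,
    write_leds,
)
from .multiple_testing import group_diagnostics, grouped_local_fdr

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_huge"]


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    essentiality_path: str
    mutations_path: str
    expression_path: str
    cohort_label: str
    cohort_samples: list[str] = field(default_factory=list)
    preset: str = "generic"  # or "aml"
    edge_list_path: str | None = None

    # stage parameters (defaults: generic preset)
    knn_k: int = 10
    essential_score_cutoff: float = -2.0
    min_fraction_cohort: float = 0.20
    max_fraction_other: float = 0.10
    expression_tpm_cutoff: float = 1.0
    min_fraction_expressed: float = 0.75
    min_group_size: int = 2
    max_p: float = 0.05
    max_lfdr: float = 0.6
    min_abs_delta: float = 2.0
    fdr_level: float = 0.20
    relation_min_score: int = 400
    use_relation_filter: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in ("generic", "aml"):
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.preset == "aml":
            self.min_fraction_cohort = AML_PRESET.min_fraction_cohort
            self.use_relation_filter = True

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    def filter_params(self) -> EssentialityFilterParams:
        return EssentialityFilterParams(
            essential_score_cutoff=self.essential_score_cutoff,
            min_fraction_cohort=self.min_fraction_cohort,
            max_fraction_other=self.max_fraction_other,
            expression_tpm_cutoff=self.expression_tpm_cutoff,
            min_fraction_expressed=self.min_fraction_expressed,
        )

    def thresholds(self) -> LEDThresholds:
        return LEDThresholds(
            max_p=self.max_p, max_lfdr=self.max_lfdr, min_abs_delta=self.min_abs_delta
        )


def run_huge(cfg: RunConfig, out_dir) -> Path:
    """Run the full pipeline and write results into ``out_dir``.

    Stages: sample alignment, kNN imputation, essential-gene selection for
    the cohort, per-pair moderated t-tests, per-biomarker local FDR, LED
    calling and typing, optional relation filtering, and the
    method-comparison table.  Raises with the failing stage's name on error.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": {}}

    def _stage(name: str, fn, *args, **kwargs):
        logger.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    D = _stage("read_essentiality", read_matrix, cfg.essentiality_path)
    M_raw = _stage("read_mutations", _read_mutations, cfg.mutations_path)
    X = _stage("read_expression", read_matrix, cfg.expression_path, kind="expression")
    cohort = CohortSpec(tumor_label=cfg.cohort_label, member_samples=list(cfg.cohort_samples))

    aligned = _stage("align", align_samples, D, M_raw, X, [cohort])
    cohort = aligned.cohorts[0]
    manifest["stages"]["align"] = {
        "n_samples": aligned.essentiality.n_samples,
        "dropped": aligned.dropped_samples,
    }

    D_imp = _stage("impute", knn_impute, aligned.essentiality, cfg.knn_k)

    gene_set = _stage(
        "filter_essential",
        select_essential_genes,
        D_imp, aligned.expression, cohort, cfg.filter_params(),
    )
    gene_set.to_tsv(out_dir / "essential_genes.tsv")
    selected = gene_set.selected_ids
    manifest["stages"]["filter_essential"] = {
        "n_selected": len(selected),
        "params": asdict(cfg.filter_params()),
    }
    if not selected:
        raise RuntimeError("pipeline stage 'filter_essential' failed: no essential genes pass")

    D_cohort = D_imp.subset_genes(selected).subset_samples(cohort.member_samples)
    M_cohort = aligned.mutations.subset_samples(cohort.member_samples)

    results = _stage(
        "test", stats_engine.moderated_t_test, D_cohort, M_cohort, cfg.min_group_size
    )
    with_lfdr = _stage("correct", grouped_local_fdr, results)
    stats_engine.write_results(with_lfdr, out_dir / "test_results.tsv")
    diagnostics = group_diagnostics(with_lfdr)
    diagnostics.to_csv(out_dir / "group_diagnostics.tsv", sep="\t", index=False)
    if logger.isEnabledFor(logging.INFO):
        logger.info("per-group pi0:\n%s", diagnostics.to_string(index=False))

    leds = _stage("call", call_leds, with_lfdr, cfg.thresholds())
    leds = _stage("classify", classify_leds, leds) if len(leds) else leds.assign(led_type=[])
    manifest["stages"]["call"] = {
        "n_leds": len(leds),
        "thresholds": asdict(cfg.thresholds()),
    }

    if cfg.use_relation_filter and cfg.edge_list_path:
        edges = EdgeList.read(cfg.edge_list_path)
        leds = _stage("relation_filter", relation_filter, leds, edges, cfg.relation_min_score)
        manifest["stages"]["relation_filter"] = {
            "min_score": cfg.relation_min_score,
            "n_leds": len(leds),
        }

    write_leds(leds, out_dir / "leds.tsv")
    if len(leds):
        export_bipartite_graph(leds, out_dir / "led_graph.json")

    comparison = _stage("compare", compare_methods, results, cfg.fdr_level, cfg.thresholds())
    comparison.to_csv(out_dir / "method_comparison.tsv", sep="\t", index=False)
    manifest["stages"]["compare"] = {
        "fdr_level": cfg.fdr_level,
        "counts": dict(zip(comparison["method"], comparison["n_significant"].astype(int))),
    }

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out_dir


def _read_mutations(path):
    from .core_data import MutationMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    return MutationMatrix(
        biomarker_ids=[str(g).strip() for g in df.index],
        sample_ids=[str(s).strip() for s in df.columns],
        indicator=df.to_numpy(),
    )
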