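"""End-to-end orchestration: profiles in, repositioning report out."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx

from . import io as io_formats
from .embed import CVCurve, Embedding, cmds_embed, select_dimension
from .integrate import LabelledCohort, filter_by_class_size, integrate_layers
from .layers import (
    chem_dissimilarity_matrix,
    signed_rank_profile,
    target_dissimilarity_matrix,
    wsf_dissimilarity_matrix,
)
from .matrix import DissimilarityMatrix
from .profiles import DrugProfile
from .reposition import (
    PredictionDistribution,
    RepositioningRecord,
    bootstrap_predict,
    class_flow_summary,
    final_prediction,
    repositioning_report,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the full analysis."""

    min_class_size: int = 8
    folds: int = 6
    iterations: int = 10_000
    holdout: float = 0.1
    seed: int = 0
    rank_key: str = "gloss"
    gamma: float | str = "scale"
    C: float = 1.0
    min_score: float = 0.0
    stratified: bool = False
    max_dim: int | None = None


@dataclass
class PipelineResult:
    """Everything the pipeline computes, for inspection and reporting."""

    chem: DissimilarityMatrix
    target: DissimilarityMatrix
    gex: DissimilarityMatrix
    fused: DissimilarityMatrix
    cohort: LabelledCohort
    embedding: Embedding
    cv_curve: CVCurve
    distributions: dict[str, PredictionDistribution]
    records: list[RepositioningRecord] = field(default_factory=list)
    accuracy: float = 0.0

    @property
    def holdout_accuracy(self) -> float:
        """Pooled per-prediction holdout accuracy across all iterations."""
        correct = sum(
            self.distributions[d].counts.get(self.cohort.labels[d], 0)
            for d in self.cohort.dissim.ids
        )
        total = sum(self.distributions[d].n_eval for d in self.cohort.dissim.ids)
        return correct / total if total else 0.0

    def final_predictions(self) -> dict[str, tuple[str, float]]:
        return {
            d: final_prediction(self.distributions[d])
            for d in self.cohort.dissim.ids
        }

    def flows(self) -> dict[tuple[str, str], float]:
        return class_flow_summary(self.records)


def compute_layers(
    profiles: Sequence[DrugProfile],
    ppi: nx.Graph,
    rank_key: str = "gloss",
) -> tuple[DissimilarityMatrix, DissimilarityMatrix, DissimilarityMatrix]:
    """Compute the three layer matrices, each over the drugs that carry the
    corresponding data."""
    by_id = {p.drug_id: p for p in profiles}
    chem_ids = sorted(
        d for d, p in by_id.items()
        if p.fingerprint is not None and p.fingerprint.any()
    )
    tar_ids = sorted(d for d, p in by_id.items() if p.targets)
    gex_ids = sorted(d for d, p in by_id.items() if p.expr_stats)
    chem = chem_dissimilarity_matrix(
        {d: by_id[d].fingerprint for d in chem_ids}, chem_ids
    )
    target = target_dissimilarity_matrix(
        {d: by_id[d].targets for d in tar_ids}, ppi, tar_ids
    )
    ranked = {
        d: signed_rank_profile(by_id[d].expr_stats, rank_key=rank_key)
        for d in gex_ids
    }
    gex = wsf_dissimilarity_matrix(ranked, gex_ids)
    return chem, target, gex


def run_pipeline(
    profiles: Sequence[DrugProfile],
    ppi: nx.Graph,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run the whole method on in-memory profiles.

    Layers -> fusion -> class-size filter -> classical MDS -> dimension
    selection by cross-validated SVM error -> holdout subsampling ->
    repositioning report.
    """
    chem, target, gex = compute_layers(profiles, ppi, rank_key=config.rank_key)
    fused = integrate_layers(gex, target, chem)
    labels = {p.drug_id: p.atc2 for p in profiles if p.atc2 is not None}
    cohort = filter_by_class_size(fused, labels, min_size=config.min_class_size)
    embedding = cmds_embed(cohort.dissim)
    dims = None
    if config.max_dim is not None:
        dims = list(range(1, min(config.max_dim, embedding.n_positive) + 1))
    cv_curve = select_dimension(
        embedding,
        cohort.label_list,
        folds=config.folds,
        dims=dims,
        seed=config.seed,
        gamma=config.gamma,
        C=config.C,
    )
    coords = embedding.coords[:, : cv_curve.selected_dim]
    dists = bootstrap_predict(
        coords,
        cohort.dissim.ids,
        cohort.labels,
        iterations=config.iterations,
        holdout=config.holdout,
        seed=config.seed,
        stratified=config.stratified,
        gamma=config.gamma,
        C=config.C,
    )
    records, accuracy = repositioning_report(
        dists, cohort.labels, min_score=config.min_score
    )
    return PipelineResult(
        chem=chem,
        target=target,
        gex=gex,
        fused=fused,
        cohort=cohort,
        embedding=embedding,
        cv_curve=cv_curve,
        distributions=dists,
        records=records,
        accuracy=accuracy,
    )


def run_pipeline_from_dir(
    directory: str | Path, config: PipelineConfig = PipelineConfig()
) -> PipelineResult:
    profiles, ppi = io_formats.load_cohort(directory)
    return run_pipeline(profiles, ppi, config)


def write_report(path: str | Path, result: PipelineResult) -> None:
    """Write the repositioning report as TSV (deterministic row order)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(
            "drug_id\toriginal_atc2\tpredicted_atc2\tscore\tn_eval\tis_confirmation\n"
        )
        for rec in result.records:
            fh.write(
                f"{rec.drug_id}\t{rec.original_class}\t{rec.predicted_class}\t"
                f"{rec.score:.10g}\t{rec.n_eval}\t{int(rec.is_confirmation)}\n"
            )


def write_flows(path: str | Path, result: PipelineResult) -> None:
    """Write the score-weighted class-to-class flow edge list."""
    flows = result.flows()
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("class_from\tclass_to\ttotal_score\n")
        for (a, b), w in sorted(flows.items()):
            fh.write(f"{a}\t{b}\t{w:.10g}\n")
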