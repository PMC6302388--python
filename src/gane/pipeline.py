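"""End-to-end orchestration: annotations -> embedding -> weights -> complexes."""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .attributes import AttributeData, build_affinity, build_attribute_matrix
from .core_attachment import DetectionConfig, detect_cores_and_attachments
from .embedding import (
    Embedding,
    EmbeddingConfig,
    WeightedGraph,
    build_weighted_adjacency,
    fit_embedding,
)
from .evaluation import DEFAULT_OMEGA, EvaluationReport, evaluate
from .io_formats import AnnotationTable, ComplexSet, PPINetwork


@dataclass
class PipelineResult:
    attributes: AttributeData
    embedding: Embedding
    weights: WeightedGraph
    complexes: ComplexSet


def embed_network(
    network: PPINetwork,
    annotations: AnnotationTable,
    config: EmbeddingConfig | None = None,
    clamp_negative: bool = False,
) -> tuple[AttributeData, Embedding, WeightedGraph]:
    """Attribute matrices, fitted embedding and the weighted adjacency."""
    attrs = build_affinity(build_attribute_matrix(network, annotations))
    emb = fit_embedding(network, attrs, config)
    weights = build_weighted_adjacency(emb, network, clamp_negative=clamp_negative)
    return attrs, emb, weights


def run_pipeline(
    network: PPINetwork,
    annotations: AnnotationTable,
    embed_config: EmbeddingConfig | None = None,
    detect_config: DetectionConfig | None = None,
    clamp_negative: bool = False,
) -> PipelineResult:
    """Run the full detection pipeline and keep every intermediate."""
    attrs, emb, weights = embed_network(
        network, annotations, embed_config, clamp_negative
    )
    complexes = detect_cores_and_attachments(network, weights, detect_config)
    return PipelineResult(attrs, emb, weights, complexes)


def evaluate_run(
    result: PipelineResult,
    reference: ComplexSet,
    omega: float = DEFAULT_OMEGA,
    min_size: int = 3,
) -> EvaluationReport:
    return evaluate(result.complexes, reference, omega=omega, min_size=min_size)


_SWEEPABLE = {"dim", "lam", "theta"}


def sweep_parameter(
    param: str,
    values,
    network: PPINetwork,
    annotations: AnnotationTable,
    reference: ComplexSet,
    embed_config: EmbeddingConfig | None = None,
    detect_config: DetectionConfig | None = None,
    omega: float = DEFAULT_OMEGA,
) -> pd.DataFrame:
    """Grid one hyperparameter and tabulate the evaluation per value.

    ``theta`` sweeps reuse one embedding fit; ``dim``/``lam`` refit per
    value.  Returns one row per grid point with the full metric set.
    """
    if param not in _SWEEPABLE:
        raise ValueError(f"param must be one of {sorted(_SWEEPABLE)}")
    embed_config = embed_config or EmbeddingConfig()
    detect_config = detect_config or DetectionConfig()
    rows = []
    shared = None
    if param == "theta":
        shared = embed_network(network, annotations, embed_config)
    for value in values:
        if param == "theta":
            _, _, weights = shared
            dcfg = replace(detect_config, theta=float(value))
            complexes = detect_cores_and_attachments(network, weights, dcfg)
        else:
            ecfg = replace(
                embed_config,
                **{param: int(value) if param == "dim" else float(value)},
            )
            res = run_pipeline(network, annotations, ecfg, detect_config)
            complexes = res.complexes
        report = evaluate(complexes, reference, omega=omega)
        rows.append({param: value, **report.to_dict()})
    return pd.DataFrame(rows)
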