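"""End-to-end orchestration: prune → filter → rank → detect → merge.

``predict_complexes`` wires the stages together on an in-memory network and
returns the final complex set plus a run manifest (every parameter and the
per-stage node/edge/complex counts) for reproducibility.  ``run_detect``
and ``run_evaluate`` are the file-to-file entry points.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Union

from .detection import MIN_COMPLEX_SIZE, detect_complexes, remove_duplicates
from .evaluation import DEFAULT_OMEGA, EvaluationReport, evaluate
from .merging import MergeParams, merge_all
from .network import ComplexSet, PPINetwork, load_complexes, load_network, write_complexes
from .pruning import (
    FilterParams,
    PruningParams,
    classify_proteins,
    default_prune_threshold,
    prune,
)
from .ranking import rank_proteins

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "predict_complexes", "run_detect", "run_evaluate"]


@dataclass
class PipelineConfig:
    """All tunables of the detection pipeline, with published defaults.

    ``prune_threshold=None`` selects 0.2 for weighted and 0.45 for
    unweighted networks at run time.
    """

    prune_threshold: Optional[float] = None
    prune_iterations: int = 2
    fjord_density: float = 0.1
    shore_degree: int = 1
    damping: float = 0.85
    tolerance: float = 1e-9
    max_iter: int = 200
    min_size: int = MIN_COMPLEX_SIZE
    merge_threshold: float = 0.75
    merge_penalty: float = 2.0
    overlap_mode: str = "min"
    max_passes: int = 100
    omega_threshold: float = DEFAULT_OMEGA


def predict_complexes(
    net: PPINetwork, config: PipelineConfig | None = None
) -> tuple[ComplexSet, dict]:
    """Run the full detection pipeline on a network.

    Stages: reliability pruning, noise-protein filtering, importance
    ranking, spoke-model detection (overlapping, minimum size), duplicate
    pre-filter, merging by cohesiveness, duplicate post-filter.  Returns the
    final complexes and a manifest dict recording parameters and per-stage
    counts.  An empty result is allowed (logged, not an error).
    """
    if config is None:
        config = PipelineConfig()
    threshold = (
        config.prune_threshold
        if config.prune_threshold is not None
        else default_prune_threshold(net.is_weighted)
    )
    manifest: dict = {
        "config": {**asdict(config), "prune_threshold": threshold},
        "weighted": net.is_weighted,
        "stages": {},
    }
    stages = manifest["stages"]
    stages["input"] = {"nodes": net.n_nodes, "edges": net.n_edges}

    pruned = prune(net, PruningParams(threshold, config.prune_iterations))
    stages["pruned"] = {"nodes": pruned.n_nodes, "edges": pruned.n_edges}
    log.info("pruning: %d -> %d edges", net.n_edges, pruned.n_edges)

    cls = classify_proteins(
        pruned, FilterParams(config.fjord_density, config.shore_degree)
    )
    stages["classified"] = cls.counts()
    log.info("classification: %s", stages["classified"])

    rank = rank_proteins(pruned, config.damping, config.tolerance, config.max_iter)
    stages["ranking"] = {
        "iterations": rank.iterations_run,
        "converged": rank.converged,
    }

    detected = detect_complexes(pruned, rank, cls, config.min_size)
    stages["detected"] = {"complexes": len(detected)}
    log.info("detection: %d spoke complexes", len(detected))

    deduped = remove_duplicates(detected)
    stages["pre_filtered"] = {"complexes": len(deduped)}

    merged = merge_all(
        pruned,
        deduped,
        cls,
        MergeParams(
            threshold=config.merge_threshold,
            penalty=config.merge_penalty,
            overlap_mode=config.overlap_mode,
            max_passes=config.max_passes,
        ),
        min_size=config.min_size,
    )
    final = remove_duplicates(merged)
    stages["merged"] = {"complexes": len(final)}
    if len(final) == 0:
        log.warning("pipeline produced no complexes")
    return final, manifest


def run_detect(
    network_path: Union[str, Path],
    out_path: Union[str, Path],
    weighted: bool = False,
    config: PipelineConfig | None = None,
    manifest_path: Union[str, Path, None] = None,
) -> ComplexSet:
    """Detect complexes in an edge-list file and write them to disk.

    Writes the complexes in the one-per-line catalog dialect and, when
    ``manifest_path`` is given, a JSON run manifest.  Deterministic: the
    same input and config produce byte-identical output files.
    """
    net = load_network(network_path, weighted=weighted)
    complexes, manifest = predict_complexes(net, config)
    manifest["input_path"] = str(network_path)
    write_complexes(complexes, out_path)
    if manifest_path is not None:
        Path(manifest_path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return complexes


def run_evaluate(
    predicted_path: Union[str, Path],
    reference_path: Union[str, Path],
    omega_threshold: float = DEFAULT_OMEGA,
    out_json: Union[str, Path, None] = None,
    out_tsv: Union[str, Path, None] = None,
) -> EvaluationReport:
    """Score a predicted complex file against a reference catalog file."""
    predicted = load_complexes(predicted_path)
    reference = load_complexes(reference_path)
    report = evaluate(reference, predicted, omega_threshold)
    if out_json is not None:
        Path(out_json).write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    if out_tsv is not None:
        Path(out_tsv).write_text(report.to_tsv())
    return report
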