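"""End-to-end orchestration: preprocess -> signatures -> similarity ->
(optional length optimization) -> fusion -> clustering -> survival score ->
biomarker, with a machine-readable run report.

The pipeline is deterministic given (inputs, config, seed) and never mutates
its input files.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .biomarker import BiomarkerFeature, extract_biomarker, select_cluster_pair, write_biomarker_table
from .containers import ClusterAssignment, OmicsMatrix, SimilarityMatrix, SurvivalTable
from .fusion import FusionConfig, eigengap_k, snf_fuse, spectral_clusters
from .io import align_subjects, write_omics_matrix
from .length_selection import LengthSelectionTrace, select_length
from .preprocess import preprocess_pipeline
from .rbo import choose_p, combine_sides, pairwise_similarity
from .signatures import extract_signatures, layer_rank_profiles
from .survival import ScoreResult, classification_score, km_summary

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_outputs"]

DEFAULT_CANDIDATES = (25, 50, 100, 150, 200, 250)


@dataclass
class PipelineConfig:
    """All tunable parameters of one run; every default echoes into the report."""

    n1: int | None = None  # None -> optimize over candidate_lengths
    n2: int | None = None
    candidate_lengths: tuple[int, ...] = DEFAULT_CANDIDATES
    rbo_weight: float = 0.8
    n_bins: int = 100
    fusion: FusionConfig = field(default_factory=FusionConfig)
    n_clusters: int | None = None  # None -> eigengap heuristic
    k_max: int = 8
    n_perm: int = 30_000
    cv_percentile: float = 5.0
    log_pseudo: float = 1.0
    biomarker_top_n: int = 100
    alpha: float = 0.05
    biomarker_value_mode: str = "rank"
    run_biomarker: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["candidate_lengths"] = list(self.candidate_lengths)
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    preprocess_reports: list[dict]
    length_traces: dict[str, dict]  # "<layer>/<side>" -> trace dict
    chosen_lengths: dict[str, tuple[int, int]]  # layer -> (n1, n2)
    layer_networks: list[SimilarityMatrix]
    fused: SimilarityMatrix
    assignment: ClusterAssignment
    score: ScoreResult
    biomarkers: dict[str, list[BiomarkerFeature]]
    cluster_pair: tuple[int, int] | None
    stage_seconds: dict[str, float]

    def report(self) -> dict:
        return {
            "version": __version__,
            "config": self.config.to_dict(),
            "preprocess": self.preprocess_reports,
            "length_selection": self.length_traces,
            "chosen_lengths": {k: list(v) for k, v in self.chosen_lengths.items()},
            "n_clusters": self.assignment.k,
            "cluster_method": self.assignment.method,
            "cluster_sizes": np.bincount(self.assignment.labels).tolist(),
            "score": asdict(self.score),
            "cluster_pair": list(self.cluster_pair) if self.cluster_pair else None,
            "n_biomarkers": {k: len(v) for k, v in self.biomarkers.items()},
            "stage_seconds": self.stage_seconds,
        }


def _candidate_grid(cfg: PipelineConfig, n_features: int) -> list[int]:
    cap = max(1, n_features // 2)
    cands = [c for c in cfg.candidate_lengths if c <= cap]
    if len(cands) < 2:
        cands = sorted({max(1, cap // 2), cap})
    return cands


def _layer_network(
    layer: OmicsMatrix, cfg: PipelineConfig
) -> tuple[SimilarityMatrix, tuple[int, int], dict[str, LengthSelectionTrace]]:
    """Similarity network for one preprocessed layer (auto or fixed lengths)."""
    profiles = layer_rank_profiles(layer)
    traces: dict[str, LengthSelectionTrace] = {}

    def side_matrix(side: str, n: int) -> SimilarityMatrix:
        sigs = []
        for prof in profiles:
            top, bottom = extract_signatures(prof, n, n)
            sigs.append(top if side == "top" else bottom)
        return pairwise_similarity(sigs, p=choose_p(n, cfg.rbo_weight))

    if cfg.n1 is not None and cfg.n2 is not None:
        n1, n2 = cfg.n1, cfg.n2
        m_top, m_bottom = side_matrix("top", n1), side_matrix("bottom", n2)
    else:
        candidates = _candidate_grid(cfg, layer.n_features)
        chosen: dict[str, int] = {}
        mats: dict[str, dict[int, SimilarityMatrix]] = {"top": {}, "bottom": {}}
        for side in ("top", "bottom"):
            for c in candidates:
                mats[side][c] = side_matrix(side, c)
            trace = select_length(candidates, [mats[side][c] for c in candidates], cfg.n_bins)
            traces[side] = trace
            chosen[side] = trace.selected
        n1, n2 = chosen["top"], chosen["bottom"]
        m_top, m_bottom = mats["top"][n1], mats["bottom"][n2]
    combined = combine_sides(m_top, m_bottom)
    return combined, (n1, n2), traces


def run_pipeline(
    layers: list[OmicsMatrix],
    survival: SurvivalTable,
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full stratification pipeline on in-memory inputs."""
    cfg = cfg or PipelineConfig()
    stage_seconds: dict[str, float] = {}

    def _stage(name: str):
        logger.info("stage: %s", name)
        stage_seconds[name] = _time.perf_counter()

    def _done(name: str):
        stage_seconds[name] = _time.perf_counter() - stage_seconds[name]

    _stage("align")
    layers, survival = align_subjects(layers, survival)
    _done("align")

    _stage("preprocess")
    reports = []
    processed = []
    for layer in layers:
        filtered, rep = preprocess_pipeline(
            layer, pseudo=cfg.log_pseudo, cv_percentile=cfg.cv_percentile
        )
        processed.append(filtered)
        reports.append(rep.to_dict())
    _done("preprocess")

    _stage("similarity")
    networks: list[SimilarityMatrix] = []
    chosen_lengths: dict[str, tuple[int, int]] = {}
    all_traces: dict[str, dict] = {}
    sig_store: dict[str, tuple] = {}
    for layer in processed:
        net, (n1, n2), traces = _layer_network(layer, cfg)
        networks.append(net)
        chosen_lengths[layer.layer_name] = (n1, n2)
        for side, tr in traces.items():
            all_traces[f"{layer.layer_name}/{side}"] = tr.to_dict()
        # keep final signatures for the biomarker stage
        profiles = layer_rank_profiles(layer)
        tops, bottoms = [], []
        for prof in profiles:
            t, b = extract_signatures(prof, n1, n2)
            tops.append(t)
            bottoms.append(b)
        sig_store[layer.layer_name] = (tops, bottoms)
    _done("similarity")

    _stage("fusion")
    fused = snf_fuse(networks, cfg.fusion) if len(networks) > 1 else networks[0]
    _done("fusion")

    _stage("clustering")
    if cfg.n_clusters is not None:
        k, method = cfg.n_clusters, "user-fixed"
    else:
        k, degenerate = eigengap_k(fused, k_max=min(cfg.k_max, fused.n_subjects - 1))
        method = "eigengap" + ("-degenerate" if degenerate else "")
    assignment = spectral_clusters(fused, k, seed=cfg.seed)
    assignment.method = method
    _done("clustering")

    _stage("survival")
    score = classification_score(assignment, survival, n_perm=cfg.n_perm, seed=cfg.seed)
    _done("survival")

    biomarkers: dict[str, list[BiomarkerFeature]] = {}
    pair: tuple[int, int] | None = None
    if cfg.run_biomarker:
        _stage("biomarker")
        pair = select_cluster_pair(assignment, survival)
        for layer in processed:
            tops, bottoms = sig_store[layer.layer_name]
            biomarkers[layer.layer_name] = extract_biomarker(
                layer,
                tops,
                bottoms,
                assignment,
                cluster_a=pair[0],
                cluster_b=pair[1],
                top_n=cfg.biomarker_top_n,
                alpha=cfg.alpha,
                value_mode=cfg.biomarker_value_mode,
            )
        _done("biomarker")

    return PipelineResult(
        config=cfg,
        preprocess_reports=reports,
        length_traces=all_traces,
        chosen_lengths=chosen_lengths,
        layer_networks=networks,
        fused=fused,
        assignment=assignment,
        score=score,
        biomarkers=biomarkers,
        cluster_pair=pair,
        stage_seconds={k: round(v, 3) for k, v in stage_seconds.items()},
    )


def write_outputs(result: PipelineResult, survival: SurvivalTable, outdir: str | Path) -> None:
    """Write all run artifacts (clusters, networks, score, biomarker, report)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.assignment.to_frame().to_csv(out / "clusters.csv", index=False)
    result.fused.to_frame().to_csv(
        out / "fused_network.tsv", sep="\t", index_label="subject_id", float_format="%.12g"
    )
    edges = []
    ids = result.fused.subject_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            edges.append(f"{ids[i]}\t{ids[j]}\t{result.fused.values[i, j]:.12g}")
    (out / "fused_edges.tsv").write_text(
        "subject_a\tsubject_b\tweight\n" + "\n".join(edges) + "\n"
    )
    result.score.to_json(out / "score.json")
    (out / "lengths.json").write_text(json.dumps(result.length_traces, indent=2))
    all_bm = [f for feats in result.biomarkers.values() for f in feats]
    write_biomarker_table(all_bm, out / "biomarker.tsv")
    (out / "report.json").write_text(json.dumps(result.report(), indent=2))
    try:
        km_summary(result.assignment, survival).to_csv(
            out / "km_summary.tsv", sep="\t", index=False, float_format="%.6g"
        )
    except Exception as exc:  # KM table is informational only
        logger.warning("could not write KM summary: %s", exc)
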