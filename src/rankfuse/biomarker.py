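"""Biomarker extraction from the subject-specific signatures of two clusters.

Every signature's positions are normalized to [0, 1], reversed so the most
extreme feature scores highest, and divided by the cluster size so that a
feature appearing in every subject's signature outweighs one appearing in a
few.  Top- and bottom-side scores are fused, features are ranked by their
score sum and the top candidates are kept; candidates are then filtered by a
two-sided Wilcoxon rank-sum test between the two clusters (on each feature's
per-subject rank by default, preserving the pipeline's normalization-free
character) with Bonferroni control over the candidates tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ClusterAssignment, OmicsMatrix, Signature, SurvivalTable

logger = logging.getLogger(__name__)

__all__ = [
    "BiomarkerFeature",
    "normalized_signature_scores",
    "candidate_biomarker",
    "wilcoxon_filter",
    "rank_value_matrix",
    "select_cluster_pair",
    "extract_biomarker",
    "write_biomarker_table",
]


@dataclass
class BiomarkerFeature:
    feature_id: str
    layer_name: str
    rank_sum_score: float
    raw_p: float
    adjusted_p: float
    direction: int  # sign of median rank difference (cluster A - cluster B)


def normalized_signature_scores(
    sig: Signature, n_subjects_in_group: int
) -> dict[str, float]:
    """Positional scores of one signature, frequency-normalized.

    Positions x = 1..n map to (x - min) / max(x - min), are reversed as
    1 - value (most extreme feature -> 1) and divided by the group's subject
    count.  A single-feature signature normalizes to all-zero and hence
    scores 1 / n_subjects.
    """
    if n_subjects_in_group < 1:
        raise ValueError("group must contain at least one subject")
    n = len(sig)
    x = np.arange(1, n + 1, dtype=float)
    span = (x - x.min()).max()
    if span == 0:
        logger.info(
            "single-feature signature for subject %s: degenerate normalization", sig.subject_id
        )
        normalized = np.zeros(n)
    else:
        normalized = (x - x.min()) / span
    scores = (1.0 - normalized) / n_subjects_in_group
    return dict(zip(sig.feature_ids, scores))


def candidate_biomarker(
    cluster_subjects: Sequence[str],
    signatures: Sequence[Signature],
    top_n: int = 100,
) -> list[tuple[str, float]]:
    """Rank-sum fusion of a cluster's top and bottom signatures.

    Each subject must contribute both sides; per-feature scores are summed
    over subjects and sides, features are sorted by descending score (ties
    broken by feature id) and the ``top_n`` best are returned.
    """
    subjects = set(cluster_subjects)
    if not subjects:
        raise ValueError("cluster is empty")
    sides_seen: dict[str, set[str]] = {s: set() for s in subjects}
    totals: dict[str, float] = {}
    for sig in signatures:
        if sig.subject_id not in subjects:
            continue
        sides_seen[sig.subject_id].add(sig.side)
        for f, v in normalized_signature_scores(sig, len(subjects)).items():
            totals[f] = totals.get(f, 0.0) + v
    incomplete = [s for s, sides in sides_seen.items() if sides != {"top", "bottom"}]
    if incomplete:
        raise ValueError(f"subjects without both signature sides: {sorted(incomplete)[:5]}")
    ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_n]


def wilcoxon_filter(
    features: Sequence[tuple[str, float]],
    values_A: Mapping[str, np.ndarray],
    values_B: Mapping[str, np.ndarray],
    alpha: float = 0.05,
    layer_name: str = "",
) -> list[BiomarkerFeature]:
    """Two-sided rank-sum test per candidate with Bonferroni over candidates.

    Exact enumeration is used for small tie-free samples and the normal
    approximation with tie correction otherwise (scipy's policy).  Features
    constant across both clusters get p = 1 and are never kept.
    """
    n_tests = len(features)
    kept: list[BiomarkerFeature] = []
    for feature_id, score in features:
        a = np.asarray(values_A[feature_id], dtype=float)
        b = np.asarray(values_B[feature_id], dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("both clusters need >= 2 subjects for the rank-sum test")
        if np.ptp(np.concatenate([a, b])) == 0:
            raw_p = 1.0
        else:
            raw_p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)
        adjusted = min(1.0, raw_p * n_tests)
        if adjusted < alpha:
            kept.append(
                BiomarkerFeature(
                    feature_id=feature_id,
                    layer_name=layer_name,
                    rank_sum_score=score,
                    raw_p=raw_p,
                    adjusted_p=adjusted,
                    direction=int(np.sign(np.median(a) - np.median(b))),
                )
            )
    kept.sort(key=lambda f: (-f.rank_sum_score, f.feature_id))
    return kept


def rank_value_matrix(m: OmicsMatrix) -> np.ndarray:
    """Per-subject feature ranks (1 = highest value; stable ties)."""
    ranks = np.empty_like(m.values)
    for j in range(m.n_subjects):
        order = np.argsort(-m.values[:, j], kind="stable")
        ranks[order, j] = np.arange(1, m.n_features + 1)
    return ranks


def select_cluster_pair(
    assignment: ClusterAssignment, survival: SurvivalTable
) -> tuple[int, int]:
    """The two clusters with the largest survival difference.

    Kaplan-Meier median survival per cluster where defined; clusters whose
    median is never reached fall back to the mean observed time.  Returns
    (longest-surviving, shortest-surviving).
    """
    sub = survival.subset(assignment.subject_ids)
    from lifelines import KaplanMeierFitter

    summary = []
    for j in range(assignment.k):
        sel = assignment.labels == j
        med = KaplanMeierFitter().fit(sub.time[sel], sub.event[sel]).median_survival_time_
        if not np.isfinite(med):
            med = float(sub.time[sel].mean())
        summary.append(med)
    hi = int(np.argmax(summary))
    lo = int(np.argmin(summary))
    if hi == lo:  # all clusters identical; fall back to first two
        hi, lo = 0, 1
    return hi, lo


def extract_biomarker(
    layer: OmicsMatrix,
    tops: Sequence[Signature],
    bottoms: Sequence[Signature],
    assignment: ClusterAssignment,
    cluster_a: int,
    cluster_b: int,
    top_n: int = 100,
    alpha: float = 0.05,
    value_mode: str = "rank",
) -> list[BiomarkerFeature]:
    """Full biomarker extraction between two clusters for one layer.

    ``value_mode="rank"`` tests each candidate feature's per-subject rank
    within the full rank profile; ``"value"`` tests the (preprocessed) values
    instead.
    """
    if value_mode not in ("rank", "value"):
        raise ValueError("value_mode must be 'rank' or 'value'")
    members_a = assignment.members(cluster_a)
    members_b = assignment.members(cluster_b)
    sigs_a = [s for s in tops + bottoms if s.subject_id in set(members_a)]
    candidates = candidate_biomarker(members_a, sigs_a, top_n=top_n)

    tested = rank_value_matrix(layer) if value_mode == "rank" else layer.values
    col = {s: j for j, s in enumerate(layer.subject_ids)}
    row = {f: i for i, f in enumerate(layer.feature_ids)}
    cols_a = [col[s] for s in members_a]
    cols_b = [col[s] for s in members_b]
    values_A = {f: tested[row[f], cols_a] for f, _ in candidates}
    values_B = {f: tested[row[f], cols_b] for f, _ in candidates}
    return wilcoxon_filter(candidates, values_A, values_B, alpha=alpha, layer_name=layer.layer_name)


def write_biomarker_table(features: Sequence[BiomarkerFeature], path: str | Path) -> None:
    pd.DataFrame(
        [
            (f.feature_id, f.layer_name, f.rank_sum_score, f.raw_p, f.adjusted_p, f.direction)
            for f in features
        ],
        columns=["feature_id", "layer", "rank_sum_score", "raw_p", "adjusted_p", "direction"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
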