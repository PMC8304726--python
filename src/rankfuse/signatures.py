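"""Subject-specific rank profiles and extremal signatures.

Each subject's profile within an omics layer is sorted decreasingly and
replaced by ranks; the top-n1 (most expressed) and bottom-n2 (least
expressed) features form the subject's signatures.  Because only ranks
matter, the result is invariant under any strictly increasing transform of
the values — the normalization-free property of the pipeline.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import OmicsMatrix, RankProfile, Signature

__all__ = [
    "rank_profile",
    "extract_signatures",
    "layer_rank_profiles",
    "layer_signatures",
    "write_signatures",
]


def rank_profile(
    values: Sequence[float] | np.ndarray,
    feature_ids: Sequence[str],
    subject_id: str = "",
    layer_name: str = "",
) -> RankProfile:
    """Order features by decreasing value (rank 1 = highest).

    Ties are broken by original feature order (stable sort), so the profile
    is deterministic and reproducible across runs.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) != len(feature_ids):
        raise ValueError("values and feature_ids must be 1-D of equal length")
    if len(values) < 2:
        raise ValueError("rank profile requires at least 2 features")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"subject {subject_id!r}: missing value in profile")
    # stable sort on -values keeps original order among ties
    order = np.argsort(-values, kind="stable")
    return RankProfile(
        subject_id=subject_id,
        layer_name=layer_name,
        ranked_feature_ids=[feature_ids[i] for i in order],
    )


def extract_signatures(p: RankProfile, n1: int, n2: int) -> tuple[Signature, Signature]:
    """Take the top-n1 and bottom-n2 of a rank profile.

    The bottom signature is oriented most-extreme-first (the least expressed
    feature at position 1) so the top-weighting of the similarity measure
    emphasizes the most extreme features symmetrically on both sides.
    """
    n_feat = len(p)
    if n1 < 1 or n2 < 1:
        raise ValueError("n1 and n2 must be >= 1")
    if n1 + n2 > n_feat:
        raise ValueError(f"n1 + n2 = {n1 + n2} exceeds the {n_feat} available features")
    top = Signature(p.subject_id, p.layer_name, "top", p.ranked_feature_ids[:n1])
    bottom = Signature(p.subject_id, p.layer_name, "bottom", p.ranked_feature_ids[::-1][:n2])
    return top, bottom


def layer_rank_profiles(m: OmicsMatrix) -> list[RankProfile]:
    """Rank profile of every subject in a layer, in subject order."""
    return [
        rank_profile(m.values[:, j], m.feature_ids, subject_id=s, layer_name=m.layer_name)
        for j, s in enumerate(m.subject_ids)
    ]


def layer_signatures(
    m: OmicsMatrix, n1: int, n2: int
) -> tuple[list[Signature], list[Signature]]:
    """Top and bottom signatures for every subject in a layer."""
    tops, bottoms = [], []
    for p in layer_rank_profiles(m):
        t, b = extract_signatures(p, n1, n2)
        tops.append(t)
        bottoms.append(b)
    return tops, bottoms


def write_signatures(signatures: Sequence[Signature], path: str | Path) -> None:
    """Export signatures as TSV: subject_id, layer, side, position, feature_id."""
    rows = [
        (s.subject_id, s.layer_name, s.side, pos + 1, f)
        for s in signatures
        for pos, f in enumerate(s.feature_ids)
    ]
    pd.DataFrame(
        rows, columns=["subject_id", "layer", "side", "position", "feature_id"]
    ).to_csv(path, sep="\t", index=False)
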