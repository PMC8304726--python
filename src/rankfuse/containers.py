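"""Core in-memory containers shared across the pipeline.

The pipeline moves three kinds of objects around: per-omics value matrices
(features x subjects), per-subject ranked feature lists (signatures), and
subject x subject similarity matrices.  All of them are thin dataclasses over
numpy arrays with identifier bookkeeping and invariant checks at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "SurvivalTable",
    "RankProfile",
    "Signature",
    "SimilarityMatrix",
    "ClusterAssignment",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)
    return ids


@dataclass
class OmicsMatrix:
    """One omics layer: a features x subjects real-valued matrix.

    Parameters
    ----------
    layer_name:
        Label of the modality (e.g. ``"expression"``, ``"methylation"``).
    feature_ids, subject_ids:
        Unique row / column identifiers, order-preserving.
    values:
        ``(n_features, n_subjects)`` float array; missing values are rejected.
    is_expression_like:
        Whether the layer holds count-like intensities that should be
        log-transformed before z-scoring (expression, miRNA) as opposed to
        already-bounded quantities such as methylation beta values.
    """

    layer_name: str
    feature_ids: list[str]
    subject_ids: list[str]
    values: np.ndarray
    is_expression_like: bool = True

    def __post_init__(self) -> None:
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        self.subject_ids = _check_unique(self.subject_ids, "subject")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.feature_ids), len(self.subject_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"({len(self.feature_ids)}, {len(self.subject_ids)}) ids"
            )
        if self.values.size == 0:
            raise ValueError(f"layer {self.layer_name!r}: empty matrix")
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"layer {self.layer_name!r}: missing/non-finite value at "
                f"feature {self.feature_ids[r]!r}, subject {self.subject_ids[c]!r}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.subject_ids)

    def subset_subjects(self, subject_ids: Sequence[str]) -> "OmicsMatrix":
        """Restrict to ``subject_ids`` in the given order."""
        idx = {s: j for j, s in enumerate(self.subject_ids)}
        cols = [idx[s] for s in subject_ids]
        return replace(
            self,
            subject_ids=list(subject_ids),
            values=self.values[:, cols],
        )

    def subset_features(self, keep: np.ndarray) -> "OmicsMatrix":
        """Restrict to the boolean feature mask ``keep`` (row order preserved)."""
        keep = np.asarray(keep, dtype=bool)
        return replace(
            self,
            feature_ids=[f for f, k in zip(self.feature_ids, keep) if k],
            values=self.values[keep, :],
        )


@dataclass
class SurvivalTable:
    """Overall-survival records: time on study and event indicator per subject."""

    subject_ids: list[str]
    time: np.ndarray  # positive, same unit throughout (e.g. days)
    event: np.ndarray  # 1 = death observed, 0 = censored

    def __post_init__(self) -> None:
        self.subject_ids = _check_unique(self.subject_ids, "subject")
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.subject_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length must match subject_ids")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("all survival times must be finite and > 0")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")

    def subset(self, subject_ids: Sequence[str]) -> "SurvivalTable":
        idx = {s: j for j, s in enumerate(self.subject_ids)}
        missing = [s for s in subject_ids if s not in idx]
        if missing:
            raise KeyError(f"subjects missing from survival table: {missing[:5]}")
        rows = [idx[s] for s in subject_ids]
        return SurvivalTable(list(subject_ids), self.time[rows], self.event[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": self.subject_ids, "time": self.time, "event": self.event}
        )


@dataclass
class RankProfile:
    """A subject's features ordered by decreasing value (rank 1 = highest)."""

    subject_id: str
    layer_name: str
    ranked_feature_ids: list[str]

    def __post_init__(self) -> None:
        if len(set(self.ranked_feature_ids)) != len(self.ranked_feature_ids):
            raise ValueError("rank profile contains duplicate features")

    def __len__(self) -> int:
        return len(self.ranked_feature_ids)


@dataclass
class Signature:
    """Ordered extremal feature list of one subject in one omics.

    ``side == "top"`` lists the most-expressed features, highest first;
    ``side == "bottom"`` lists the least-expressed, lowest first, so both
    sides put the most extreme feature at position 1.
    """

    subject_id: str
    layer_name: str
    side: str  # "top" | "bottom"
    feature_ids: list[str]

    def __post_init__(self) -> None:
        if self.side not in ("top", "bottom"):
            raise ValueError(f"side must be 'top' or 'bottom', got {self.side!r}")
        if len(self.feature_ids) < 1:
            raise ValueError("signature must contain at least one feature")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("signature contains duplicate features")

    def __len__(self) -> int:
        return len(self.feature_ids)


@dataclass
class SimilarityMatrix:
    """Symmetric subjects x subjects similarity in [0, 1] with unit diagonal."""

    subject_ids: list[str]
    values: np.ndarray
    layer_name: str = ""
    side: str = "combined"  # "top" | "bottom" | "combined" | "fused"
    signature_length: int | None = None
    p: float | None = None

    def __post_init__(self) -> None:
        self.subject_ids = _check_unique(self.subject_ids, "subject")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.subject_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape must match subject count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_subjects, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.subject_ids)

    def permute(self, order: Sequence[int]) -> "SimilarityMatrix":
        order = list(order)
        return replace(
            self,
            subject_ids=[self.subject_ids[i] for i in order],
            values=self.values[np.ix_(order, order)],
        )


@dataclass
class ClusterAssignment:
    """Subject -> cluster-label mapping with label-range invariants."""

    subject_ids: list[str]
    labels: np.ndarray
    k: int
    method: str = "user-fixed"  # or "eigengap"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.subject_ids = _check_unique(self.subject_ids, "subject")
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.subject_ids),):
            raise ValueError("labels length must match subject count")
        if self.labels.min() < 0 or self.labels.max() >= self.k:
            raise ValueError("labels out of range 0..k-1")
        present = np.unique(self.labels)
        if len(present) != self.k:
            raise ValueError("every cluster must be non-empty")

    def members(self, label: int) -> list[str]:
        return [s for s, l in zip(self.subject_ids, self.labels) if l == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": self.subject_ids, "cluster": self.labels})
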