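"""Signature-length selection via Kullback-Leibler divergence.

To pick a signature length without arbitrary choices, a similarity matrix is
built for every candidate length, each matrix's off-diagonal values are
histogrammed on [0, 1] (pseudo-count of one per bin, normalized to sum 1),
and the divergence D_KL(P || Q) = sum_i P(i) log2(P(i)/Q(i)) of every
candidate's distribution P against the shortest candidate's distribution Q
is computed.  The selected length is where the divergence first reaches its
maximum — the best information/noise trade-off; longer is not always more
informative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .containers import SimilarityMatrix

__all__ = [
    "BinnedDistribution",
    "LengthSelectionTrace",
    "bin_similarities",
    "kl_divergence",
    "select_length",
]


@dataclass
class BinnedDistribution:
    """Histogram probabilities over equal-width bins on [0, 1].

    Pseudo-counting guarantees strictly positive probabilities, so KL ratios
    are always finite.
    """

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.bin_edges) != len(self.probabilities) + 1:
            raise ValueError("need len(bin_edges) == len(probabilities) + 1")
        if np.any(self.probabilities <= 0):
            raise ValueError("probabilities must be strictly positive")
        if abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")


@dataclass
class LengthSelectionTrace:
    """Candidates, their divergences against the shortest, and the pick."""

    candidates: list[int]
    dkl_values: list[float]
    selected: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def bin_similarities(M: SimilarityMatrix, n_bins: int = 100) -> BinnedDistribution:
    """Histogram the strictly-upper-triangle similarities with +1 per bin."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    counts, edges = np.histogram(M.upper_triangle(), bins=n_bins, range=(0.0, 1.0))
    counts = counts + 1  # pseudo-count before normalization
    return BinnedDistribution(bin_edges=edges, probabilities=counts / counts.sum())


def kl_divergence(P: BinnedDistribution, Q: BinnedDistribution) -> float:
    """D_KL(P || Q) in bits; requires identical binning."""
    if len(P.probabilities) != len(Q.probabilities) or not np.allclose(
        P.bin_edges, Q.bin_edges, atol=1e-12
    ):
        raise ValueError("distributions must share bin edges")
    return float(np.sum(P.probabilities * np.log2(P.probabilities / Q.probabilities)))


def select_length(
    candidates: Sequence[int],
    matrices: Sequence[SimilarityMatrix],
    n_bins: int = 100,
) -> LengthSelectionTrace:
    """First-maximum rule over the divergence trace.

    The reference Q is the shortest candidate's distribution; the selected
    length is the smallest candidate whose divergence equals the maximum, so
    plateaus and ties resolve to the earliest.  The shortest candidate can
    only win when every divergence is zero.
    """
    candidates = [int(c) for c in candidates]
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate lengths")
    if sorted(candidates) != candidates:
        raise ValueError("candidates must be ascending")
    if len(candidates) != len(matrices):
        raise ValueError("one similarity matrix required per candidate")
    subjects = matrices[0].subject_ids
    for m in matrices[1:]:
        if m.subject_ids != subjects:
            raise ValueError("all matrices must cover identical subjects")
    q = bin_similarities(matrices[0], n_bins=n_bins)
    dkl = [kl_divergence(bin_similarities(m, n_bins=n_bins), q) for m in matrices]
    selected = candidates[int(np.argmax(dkl))]  # argmax takes the first maximum
    return LengthSelectionTrace(candidates=candidates, dkl_values=dkl, selected=selected)
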