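"""Rank-biased overlap (RBO) similarity between equal-length signatures.

RBO compares two ranked lists through their prefix overlaps, geometrically
down-weighted by a persistence parameter ``p`` so that agreement near the top
of the lists counts most.  On depth-``k`` prefixes the extrapolated form is

    RBO(S, T, p, k) = X_k / k * p**k + (1 - p) / p * sum_d X_d / d * p**d

with ``X_d`` the size of the intersection of the two depth-``d`` prefixes.
``p`` is chosen so the whole signature depth carries a target fraction
(default 0.8) of the total evaluation mass, recomputed whenever the
signature length changes so the effective top-weighting stays stable.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

from .containers import Signature, SimilarityMatrix

__all__ = [
    "rbo_ext",
    "prefix_weight",
    "choose_p",
    "pairwise_similarity",
    "combine_sides",
    "spearman_footrule_similarity",
]


def _check_p(p: float) -> None:
    if not 0.0 < p < 1.0:
        raise ValueError(f"persistence parameter p must be in (0, 1), got {p}")


def rbo_ext(S: Signature | Sequence[str], T: Signature | Sequence[str], p: float) -> float:
    """Extrapolated RBO between two equal-length lists of unique elements."""
    _check_p(p)
    s = list(S.feature_ids if isinstance(S, Signature) else S)
    t = list(T.feature_ids if isinstance(T, Signature) else T)
    if len(s) != len(t):
        raise ValueError(f"signatures must have equal length, got {len(s)} and {len(t)}")
    k = len(s)
    if k == 0:
        raise ValueError("signatures must be non-empty")
    # incremental prefix intersections: X_d from X_{d-1} plus the new elements
    seen_s: set[str] = set()
    seen_t: set[str] = set()
    x = 0
    agreement_sum = 0.0
    x_k = 0
    for d in range(1, k + 1):
        es, et = s[d - 1], t[d - 1]
        if es == et:
            x += 1
        else:
            if es in seen_t:
                x += 1
            if et in seen_s:
                x += 1
            seen_s.add(es)
            seen_t.add(et)
        agreement_sum += x / d * p**d
        x_k = x
    return x_k / k * p**k + (1.0 - p) / p * agreement_sum


def prefix_weight(p: float, d: int) -> float:
    """Fraction of the total RBO evaluation mass carried by ranks 1..d.

    Strictly decreasing in ``p``: small p concentrates all weight on rank 1
    (weight -> 1), p -> 1 spreads it over unbounded depth (weight -> 0).
    """
    _check_p(p)
    if d < 1:
        raise ValueError("depth d must be >= 1")
    tail = math.log1p(-p) * -1.0  # ln(1/(1-p))
    partial = sum(p**i / i for i in range(1, d))
    return 1.0 - p ** (d - 1) + (1.0 - p) / p * d * (tail - partial)


def choose_p(k: int, weight: float = 0.8, tol: float = 1e-10) -> float:
    """Solve for the persistence p giving the top-k prefix the target weight.

    Because :func:`prefix_weight` is monotone decreasing in p, bisection on
    (0, 1) converges; p grows with k at fixed weight (a longer signature can
    carry the same mass with slower decay).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 < weight < 1.0:
        raise ValueError("weight must be in (0, 1)")
    lo, hi = 1e-12, 1.0 - 1e-12
    f_lo = prefix_weight(lo, k) - weight
    f_hi = prefix_weight(hi, k) - weight
    if f_lo < 0 or f_hi > 0:
        raise ValueError(f"no persistence value in (0,1) gives weight {weight} at k={k}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if prefix_weight(mid, k) - weight > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _signatures_to_int_matrix(signatures: Sequence[Signature]) -> np.ndarray:
    """Encode a set of equal-length signatures as an (n, k) int array."""
    vocab: dict[str, int] = {}
    k = len(signatures[0])
    out = np.empty((len(signatures), k), dtype=np.int64)
    for i, sig in enumerate(signatures):
        if len(sig) != k:
            raise ValueError("all signatures must have the same length")
        for a, f in enumerate(sig.feature_ids):
            out[i, a] = vocab.setdefault(f, len(vocab))
    return out


def pairwise_similarity(
    signatures: Sequence[Signature],
    p: float | None = None,
    weight: float = 0.8,
    measure: Callable[[Signature, Signature], float] | None = None,
) -> SimilarityMatrix:
    """Subject x subject similarity matrix from one signature per subject.

    All signatures must belong to the same layer and side and share one
    length.  Only the upper triangle is computed and mirrored; the diagonal
    is forced to 1.  With ``measure=None`` the RBO of the module is used via
    a vectorized prefix-overlap recurrence; any callable ``(S, T) -> float``
    may be plugged in instead (e.g. :func:`spearman_footrule_similarity`).
    """
    n = len(signatures)
    if n < 2:
        raise ValueError("pairwise similarity requires at least 2 subjects")
    layer = signatures[0].layer_name
    side = signatures[0].side
    k = len(signatures[0])
    for s in signatures:
        if s.layer_name != layer or s.side != side or len(s) != k:
            raise ValueError("signatures must share layer, side and length")

    values = np.eye(n)
    if measure is not None:
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = measure(signatures[i], signatures[j])
        return SimilarityMatrix(
            subject_ids=[s.subject_id for s in signatures],
            values=values,
            layer_name=layer,
            side=side,
            signature_length=k,
            p=None,
        )

    if p is None:
        p = choose_p(k, weight)
    _check_p(p)
    codes = _signatures_to_int_matrix(signatures)
    n_vocab = int(codes.max()) + 1
    pd_weights = p ** np.arange(1, k + 1) / np.arange(1, k + 1)  # p^d / d
    depth = np.arange(1, k + 1)

    # position of each vocabulary item within each signature (k if absent)
    pos = np.full((n, n_vocab), k, dtype=np.int64)
    rows = np.repeat(np.arange(n), k)
    pos[rows, codes.ravel()] = np.tile(np.arange(k), n)

    for i in range(n - 1):
        others = np.arange(i + 1, n)
        # element S_i[a] enters the joint prefix at depth max(a+1, pos_in_T+1)
        pos_in_others = pos[others][:, codes[i]]  # (m, k), 0-based or k
        entry_depth = np.maximum(depth[None, :], pos_in_others + 1)  # 1..k or k+1
        counts = np.zeros((len(others), k + 2), dtype=np.int64)
        np.add.at(counts, (np.repeat(np.arange(len(others)), k), entry_depth.ravel()), 1)
        x = np.cumsum(counts[:, 1 : k + 1], axis=1)  # X_d for d = 1..k
        sim = x[:, -1] / k * p**k + (1.0 - p) / p * (x @ pd_weights)
        values[i, others] = sim
        values[others, i] = sim

    return SimilarityMatrix(
        subject_ids=[s.subject_id for s in signatures],
        values=values,
        layer_name=layer,
        side=side,
        signature_length=k,
        p=p,
    )


def combine_sides(M_top: SimilarityMatrix, M_bottom: SimilarityMatrix) -> SimilarityMatrix:
    """Entrywise mean of the top-side and bottom-side similarity matrices."""
    if M_top.subject_ids != M_bottom.subject_ids:
        raise ValueError("top and bottom matrices must share subjects and order")
    return SimilarityMatrix(
        subject_ids=list(M_top.subject_ids),
        values=0.5 * (M_top.values + M_bottom.values),
        layer_name=M_top.layer_name,
        side="combined",
        signature_length=M_top.signature_length,
        p=M_top.p,
    )


def spearman_footrule_similarity(S: Signature | Sequence[str], T: Signature | Sequence[str]) -> float:
    """Footrule-based similarity on equal-length lists (reference measure).

    Absent elements are assigned position k; the summed displacement is
    normalized by its disjoint-lists maximum k*(k+1), giving 1 for identical
    and 0 for disjoint lists.  Shipped as the alternative-measure reference
    for tests; RBO is the production measure.
    """
    s = list(S.feature_ids if isinstance(S, Signature) else S)
    t = list(T.feature_ids if isinstance(T, Signature) else T)
    if len(s) != len(t):
        raise ValueError("signatures must have equal length")
    k = len(s)
    pos_s = {f: i for i, f in enumerate(s)}
    pos_t = {f: i for i, f in enumerate(t)}
    d = 0
    for f in set(s) | set(t):
        d += abs(pos_s.get(f, k) - pos_t.get(f, k))
    return 1.0 - d / (k * (k + 1))
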