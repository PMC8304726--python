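"""Per-layer preprocessing: log transform, z-scoring and variation filters.

The pipeline consumes each layer after (i) optional log transform for
count-like modalities, (ii) removal of zero-variance features, (iii) per-
feature z-scoring to mean 0 / sd 1, and (iv) removal of features whose
coefficient of variation falls below a percentile cut.  The CV (sigma/mu) is
degenerate on z-scored rows (mu = 0), so it is computed on the post-log,
pre-scaling values as |sigma/mu|; the filter is then applied to the scaled
matrix.  Population (1/n) standard deviation is used throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .containers import OmicsMatrix

logger = logging.getLogger(__name__)

__all__ = ["PreprocessReport", "preprocess_layer", "filter_low_cv", "preprocess_pipeline"]


@dataclass
class PreprocessReport:
    """Per-layer bookkeeping of how many features each filter removed."""

    layer_name: str
    n_features_in: int
    n_removed_zero_variance: int = 0
    n_removed_low_cv: int = 0
    cv_threshold_value: float | None = None
    n_infinite_cv: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def n_features_out(self) -> int:
        return self.n_features_in - self.n_removed_zero_variance - self.n_removed_low_cv

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_features_out"] = self.n_features_out
        return d


def _row_sd(values: np.ndarray) -> np.ndarray:
    # population sd (ddof=0), the documented constant choice
    return values.std(axis=1, ddof=0)


def preprocess_layer(
    m: OmicsMatrix,
    do_log: bool | None = None,
    pseudo: float = 1.0,
    report: PreprocessReport | None = None,
) -> tuple[OmicsMatrix, OmicsMatrix, PreprocessReport]:
    """Log-transform (optional), drop zero-variance features and z-score.

    Returns ``(scaled, post_log_raw, report)`` where ``post_log_raw`` holds
    the post-log, pre-scaling values of the surviving features — the scale on
    which :func:`filter_low_cv` computes the coefficient of variation.

    ``do_log=None`` defers to ``m.is_expression_like``.  The log transform is
    natural log of ``value + pseudo`` and requires nonnegative input.
    """
    if do_log is None:
        do_log = m.is_expression_like
    report = report or PreprocessReport(layer_name=m.layer_name, n_features_in=m.n_features)
    values = m.values
    if do_log:
        if np.any(values < 0):
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"layer {m.layer_name!r}: negative value at feature "
                f"{m.feature_ids[r]!r} cannot be log-transformed"
            )
        values = np.log(values + pseudo)

    sd = _row_sd(values)
    keep = sd > 0.0
    report.n_removed_zero_variance = int((~keep).sum())
    if not keep.any():
        raise ValueError(f"layer {m.layer_name!r}: all features have zero variance")

    raw = OmicsMatrix(
        layer_name=m.layer_name,
        feature_ids=[f for f, k in zip(m.feature_ids, keep) if k],
        subject_ids=list(m.subject_ids),
        values=values[keep, :],
        is_expression_like=m.is_expression_like,
    )
    mu = raw.values.mean(axis=1, keepdims=True)
    sigma = _row_sd(raw.values)[:, None]
    scaled = OmicsMatrix(
        layer_name=m.layer_name,
        feature_ids=list(raw.feature_ids),
        subject_ids=list(m.subject_ids),
        values=(raw.values - mu) / sigma,
        is_expression_like=m.is_expression_like,
    )
    return scaled, raw, report


def filter_low_cv(
    m_raw: OmicsMatrix,
    m_scaled: OmicsMatrix,
    percentile: float = 5.0,
    report: PreprocessReport | None = None,
) -> tuple[OmicsMatrix, PreprocessReport]:
    """Drop features whose |CV| is strictly below the given percentile.

    CV = |sigma/mu| on the pre-normalization (post-log) values ``m_raw``.
    Features with mu = 0 get CV = +inf (never filtered, counted in the
    report).  The threshold is the linear-interpolation percentile of the CV
    distribution; removal uses strict ``<`` so an all-tied distribution drops
    nothing.
    """
    if m_raw.feature_ids != m_scaled.feature_ids:
        raise ValueError("raw and scaled matrices must share feature ids")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    report = report or PreprocessReport(
        layer_name=m_scaled.layer_name, n_features_in=m_scaled.n_features
    )
    mu = m_raw.values.mean(axis=1)
    sigma = _row_sd(m_raw.values)
    with np.errstate(divide="ignore"):
        cv = np.abs(np.divide(sigma, mu, out=np.full_like(sigma, np.inf), where=mu != 0))
    cv[mu == 0] = np.inf
    report.n_infinite_cv = int(np.isinf(cv).sum())
    if report.n_infinite_cv:
        logger.info(
            "layer %s: %d features with mu=0 assigned CV=+inf (never filtered)",
            m_scaled.layer_name,
            report.n_infinite_cv,
        )
    finite = cv[np.isfinite(cv)]
    threshold = float(np.percentile(finite if finite.size else cv, percentile))
    keep = ~(cv < threshold)  # strict "<": ties at the threshold survive
    report.cv_threshold_value = threshold
    report.n_removed_low_cv = int((~keep).sum())
    return m_scaled.subset_features(keep), report


def preprocess_pipeline(
    m: OmicsMatrix,
    do_log: bool | None = None,
    pseudo: float = 1.0,
    cv_percentile: float = 5.0,
) -> tuple[OmicsMatrix, PreprocessReport]:
    """Full per-layer preprocessing: log -> zero-variance -> z-score -> CV filter."""
    scaled, raw, report = preprocess_layer(m, do_log=do_log, pseudo=pseudo)
    filtered, report = filter_low_cv(raw, scaled, percentile=cv_percentile, report=report)
    return filtered, report
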