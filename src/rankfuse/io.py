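"""Reading and writing the pipeline's TSV interchange formats.

Omics matrices are tab-separated text: header row of subject ids, first
column feature ids, '.' decimal separator.  Survival tables are TSV with
columns ``subject_id``, ``time``, ``event``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import OmicsMatrix, SurvivalTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_omics_matrix",
    "write_omics_matrix",
    "read_survival_table",
    "write_survival_table",
    "align_subjects",
]


def read_omics_matrix(
    path: str | Path, layer_name: str, is_expression_like: bool = True
) -> OmicsMatrix:
    """Load a features x subjects TSV into an :class:`OmicsMatrix`.

    Row/column order is preserved from the file.  Duplicated ids, empty
    matrices and non-numeric cells (including ``NA``) are errors — missing
    values are rejected, never imputed.
    """
    # pandas silently renames duplicate header columns, so check them raw
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for s in header:
        if s in seen:
            raise ValueError(f"{path}: duplicate subject id {s!r} in header")
        seen.add(s)
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty matrix")
    features = [str(f) for f in df.index]
    subjects = [str(s) for s in df.columns]
    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            try:
                v = float(raw[i, j])
            except ValueError:
                v = np.nan
            if not np.isfinite(v):
                raise ValueError(
                    f"{path}: non-numeric cell {raw[i, j]!r} at "
                    f"feature {features[i]!r} (row {i + 2}), "
                    f"subject {subjects[j]!r} (column {j + 2})"
                )
            values[i, j] = v
    return OmicsMatrix(
        layer_name=layer_name,
        feature_ids=features,
        subject_ids=subjects,
        values=values,
        is_expression_like=is_expression_like,
    )


def write_omics_matrix(m: OmicsMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="feature_id", float_format="%.12g")


def read_survival_table(path: str | Path) -> SurvivalTable:
    """Load a TSV with mandatory columns subject_id, time, event (0/1)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("subject_id", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    return SurvivalTable(
        subject_ids=[str(s) for s in df["subject_id"]],
        time=df["time"].to_numpy(dtype=float),
        event=df["event"].to_numpy(dtype=int),
    )


def write_survival_table(t: SurvivalTable, path: str | Path) -> None:
    t.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def align_subjects(
    layers: list[OmicsMatrix], survival: SurvivalTable
) -> tuple[list[OmicsMatrix], SurvivalTable]:
    """Restrict all layers and the survival table to their common subjects.

    The intersection is taken over every layer and the survival table and the
    outputs share one canonical (sorted) subject order, so downstream
    matrices are directly comparable across layers.
    """
    if len(layers) < 2:
        raise ValueError("align_subjects requires at least 2 layers")
    common = set(layers[0].subject_ids)
    for layer in layers[1:]:
        common &= set(layer.subject_ids)
    common &= set(survival.subject_ids)
    if not common:
        raise ValueError("no subjects shared by all layers and the survival table")
    order = sorted(common)
    logger.info("align_subjects: %d common subjects across %d layers", len(order), len(layers))
    return [m.subset_subjects(order) for m in layers], survival.subset(order)
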