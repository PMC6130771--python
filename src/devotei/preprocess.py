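"""Normalization, low-expression filtering, transforms and expressed-calls.

CPM normalization rescales each stage column to a fixed library size of
10⁶ without transcript-length correction — appropriate for 3'-tag
protocols (e.g. CEL-Seq) where read counts are independent of transcript
length.  The low-mean filter removes genes whose mean linear expression
across stages falls below a threshold (default 1), guarding against the
large technical error of lowly expressed genes in single-embryo data.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix

__all__ = [
    "ExpressionCallMatrix",
    "normalize_cpm",
    "filter_low_mean",
    "transform_expression",
    "call_expressed",
]

TRANSFORM_MODES = ("log2", "sqrt", "identity")


@dataclass
class ExpressionCallMatrix:
    """Boolean expressed/not-expressed calls, same shape as the source matrix."""

    calls: pd.DataFrame  # genes × stages, bool
    rule: str

    @property
    def gene_ids(self) -> pd.Index:
        return self.calls.index

    @property
    def stage_ids(self) -> list[str]:
        return list(self.calls.columns)


def normalize_cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each stage column of a raw count matrix to sum to 10⁶.

    Counts-per-million without transcript-length normalization; the output
    is on the ``normalized_linear`` scale.  Idempotent up to rounding.
    """
    if m.scale != "raw_count":
        raise ValueError(f"normalize_cpm expects raw_count input, got {m.scale!r}")
    colsums = m.data.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero):
        raise ValueError(f"all-zero stage column(s): {list(zero.index)}")
    data = m.data * (1e6 / colsums)
    return ExpressionMatrix(data=data, scale="normalized_linear")


def filter_low_mean(m: ExpressionMatrix, threshold: float = 1.0) -> ExpressionMatrix:
    """Drop genes whose mean expression across stages is strictly below *threshold*.

    Removal is strict (< threshold): a gene whose mean equals the threshold
    is retained.  Gene order is preserved.
    """
    if m.scale == "log_transformed":
        raise ValueError("filter_low_mean operates on linear-scale expression")
    keep = m.data.mean(axis=1) >= threshold
    return m.with_data(m.data.loc[keep])


def transform_expression(m: ExpressionMatrix, mode: str) -> ExpressionMatrix:
    """Apply the expression-value transform used to weight the indexes.

    ``log2`` computes log2(x+1): the pseudocount maps 0 → 0 and keeps the
    weights nonnegative, the conventional choice for FPKM/CPM data.
    ``sqrt`` computes √x (no pseudocount needed).  ``identity`` passes
    through, and is the only mode accepted for already-log-transformed
    input.
    """
    if mode not in TRANSFORM_MODES:
        raise ValueError(f"unknown transform mode {mode!r}; expected one of {TRANSFORM_MODES}")
    if m.scale == "log_transformed":
        if mode != "identity":
            raise ValueError(
                "input is already log-transformed; only the identity transform is valid"
            )
        return m.with_data(m.data.copy())
    if mode == "identity":
        return m.with_data(m.data.copy())
    if mode == "log2":
        return ExpressionMatrix(data=np.log2(m.data + 1.0), scale="log_transformed")
    return ExpressionMatrix(data=np.sqrt(m.data), scale="normalized_linear")


def call_expressed(
    m: ExpressionMatrix,
    rule: str = "threshold",
    *,
    threshold: float = 1.0,
    q: float = 0.7,
) -> ExpressionCallMatrix:
    """Binarize expression into expressed / not-expressed calls.

    ``rule="threshold"`` calls a gene expressed at a stage when its value is
    strictly greater than *threshold* (e.g. FPKM > 1); linear-scale input
    only.  ``rule="rank_top"`` calls, within each stage independently, the
    genes whose expression rank (descending, ties by average rank) is within
    the top ⌈q·G⌉ positions — usable on any scale since it depends only on
    within-stage ranks.
    """
    if rule == "threshold":
        if m.scale == "log_transformed":
            raise ValueError("threshold calls require linear-scale expression")
        calls = m.data > threshold
        tag = f"threshold:{threshold:g}"
    elif rule == "rank_top":
        if not (0 < q <= 1):
            raise ValueError(f"rank_top fraction q must be in (0, 1], got {q}")
        n_genes = m.data.shape[0]
        cutoff = int(np.ceil(q * n_genes))
        ranks = np.apply_along_axis(lambda col: rankdata(-col, method="average"), 0, m.data.to_numpy())
        calls = pd.DataFrame(ranks <= cutoff, index=m.data.index, columns=m.data.columns)
        tag = f"rank_top:{q:g}"
    else:
        raise ValueError(f"unknown call rule {rule!r}")
    return ExpressionCallMatrix(calls=calls.astype(bool), rule=tag)
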