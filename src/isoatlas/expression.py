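"""Expression dynamics: ZGA calls, splicing-factor correlations, z-scores,
and quantification-change flags between annotation references.

A ZGA (zygotic genome activation) transcript/gene is one that is silent
in the oocyte (<= 1 TPM/FPKM), expressed (> 1) in both 1-cell and
2-cell, with 2-cell expression more than twice the 1-cell level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

EXPRESSION_THRESHOLD = 1.0
ZGA_FOLD = 2.0
DELTA_THRESHOLD = 5.0


@dataclass(frozen=True)
class ZgaCall:
    feature_id: str
    oocyte: float
    one_cell: float
    two_cell: float
    is_zga: bool
    unit: str


def call_zga(
    expr: ExpressionMatrix,
    oocyte_stage: str = "Oo",
    one_cell_stage: str = "1C",
    two_cell_stage: str = "2C",
    threshold: float = EXPRESSION_THRESHOLD,
    fold: float = ZGA_FOLD,
) -> List[ZgaCall]:
    """ZGA calls from stage-averaged expression.

    Replicate columns are averaged per stage before the four clauses are
    evaluated: oocyte <= threshold, 1C > threshold, 2C > threshold, and
    2C > fold x 1C.
    """
    means = expr.stage_means()
    for stage in (oocyte_stage, one_cell_stage, two_cell_stage):
        if stage not in means.columns:
            raise KeyError(f"stage {stage!r} missing from expression matrix")
    calls = []
    for fid, row in means.iterrows():
        oo = float(row[oocyte_stage])
        c1 = float(row[one_cell_stage])
        c2 = float(row[two_cell_stage])
        is_zga = (
            oo <= threshold and c1 > threshold and c2 > threshold and c2 > fold * c1
        )
        calls.append(ZgaCall(str(fid), oo, c1, c2, is_zga, expr.unit))
    return calls


def sf_as_correlation(
    sf_expr: pd.DataFrame,
    as_counts: Mapping[str, float],
) -> Dict[str, Optional[float]]:
    """Pearson correlation between each splicing factor's per-stage
    expression and the per-stage AS event totals.

    ``sf_expr`` rows are factors, columns are stages.  A factor with
    zero variance in either vector gets None.
    """
    stages = [s for s in sf_expr.columns if s in as_counts]
    if len(stages) < 3:
        raise ValueError("need >= 3 paired stage observations")
    counts = np.array([as_counts[s] for s in stages], dtype=float)
    out: Dict[str, Optional[float]] = {}
    for factor, row in sf_expr[stages].iterrows():
        x = row.to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(counts) == 0:
            out[str(factor)] = None
        else:
            out[str(factor)] = float(np.corrcoef(x, counts)[0, 1])
    return out


def stage_zscore(values: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores ((x - mean) / sd, population sd); constant rows
    emit zeros."""
    if values.shape[1] < 2:
        raise ValueError("z-scores need >= 2 samples per row")
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mean) / sd
    z[np.repeat(sd == 0, arr.shape[1], axis=1)] = 0.0
    return pd.DataFrame(z, index=values.index, columns=values.columns)


@dataclass(frozen=True)
class QuantChangeFlag:
    transcript_id: str
    delta_per_stage: Dict[str, float]
    flagged: bool


def quant_change_flags(
    counts_ref_a: pd.DataFrame,
    counts_ref_b: pd.DataFrame,
    delta_threshold: float = DELTA_THRESHOLD,
    mode: str = "ratio",
) -> List[QuantChangeFlag]:
    """Flag transcripts whose mapped-read counts change by delta > 5 in
    >= 1 stage between two annotation references.

    delta is the pseudocounted fold change max(a+1, b+1) / min(a+1, b+1)
    (mode="ratio", default) or the absolute difference |a - b|
    (mode="difference").
    """
    if mode not in ("ratio", "difference"):
        raise ValueError(f"unknown delta mode {mode!r}")
    if not counts_ref_a.index.equals(counts_ref_b.index) or not list(
        counts_ref_a.columns
    ) == list(counts_ref_b.columns):
        raise ValueError("count tables must share transcript ids and stages")
    out = []
    a_arr = counts_ref_a.to_numpy(dtype=float)
    b_arr = counts_ref_b.to_numpy(dtype=float)
    if mode == "ratio":
        hi = np.maximum(a_arr + 1, b_arr + 1)
        lo = np.minimum(a_arr + 1, b_arr + 1)
        delta = hi / lo
    else:
        delta = np.abs(a_arr - b_arr)
    stages = list(counts_ref_a.columns)
    for i, tid in enumerate(counts_ref_a.index):
        per_stage = {s: float(delta[i, j]) for j, s in enumerate(stages)}
        out.append(
            QuantChangeFlag(str(tid), per_stage, bool((delta[i] > delta_threshold).any()))
        )
    return out
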