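"""Sample- and gene-level QC and CPM normalization.

The filters mirror a fixed-depth BRB-seq quality-control recipe: a
sequencing-depth window on total counts per sample, removal of genes that
are noisy in non-OA control cartilage, a minimum-expression rule over OA
samples, and selection of the most variable genes for clustering.

Boundary semantics are exact and documented per function: the depth window
is inclusive at both ends, the minimum-CPM rule is a strict inequality, and
variances use the unbiased (n-1) denominator on log2(CPM+1).
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .io import ValidationError, read_count_matrix  # noqa: F401  (re-export)

DEPTH_LOW = 500_000
DEPTH_HIGH = 2_000_000


def filter_samples_by_depth(counts: pd.DataFrame, low: int = DEPTH_LOW,
                            high: int = DEPTH_HIGH) -> pd.DataFrame:
    """Keep samples whose total counts fall inside [low, high] (inclusive)."""
    if not low < high:
        raise ValidationError(f"depth window requires low < high, got {(low, high)}")
    totals = counts.sum(axis=0)
    keep = (totals >= low) & (totals <= high)
    if not keep.any():
        raise ValidationError(
            f"depth filter [{low}, {high}] removed every sample "
            f"(totals span {int(totals.min())}–{int(totals.max())})"
        )
    return counts.loc[:, keep]


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalization: value = count / column total × 1e6."""
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValidationError(f"zero-depth samples cannot be CPM-normalized: {zero[:5]}")
    return counts / totals * 1e6


def log2cpm(expr: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1) transform used for variance filters, HVG and clustering."""
    return np.log2(expr + 1.0)


def filter_genes_control_variance(expr: pd.DataFrame,
                                  control_samples: Sequence[str],
                                  max_variance: float = 3.0) -> pd.DataFrame:
    """Drop genes whose log2(CPM+1) variance across control samples exceeds
    ``max_variance``; retained genes keep their order."""
    control_samples = list(control_samples)
    if len(control_samples) < 2:
        raise ValidationError(
            f"control-variance filter needs >=2 control samples, got {len(control_samples)}"
        )
    missing = [s for s in control_samples if s not in expr.columns]
    if missing:
        raise ValidationError(f"control samples absent from matrix: {missing[:5]}")
    logx = log2cpm(expr[control_samples])
    var = logx.var(axis=1, ddof=1)
    return expr.loc[var <= max_variance]


def filter_genes_min_expression(expr: pd.DataFrame, oa_samples: Sequence[str],
                                min_cpm: float = 5.0,
                                min_samples: int = 15) -> pd.DataFrame:
    """Keep genes with CPM strictly greater than ``min_cpm`` in at least
    ``min_samples`` OA samples."""
    oa = expr[list(oa_samples)]
    n_pass = (oa > min_cpm).sum(axis=1)
    return expr.loc[n_pass >= min_samples]


def select_hvg(expr: pd.DataFrame, n: int = 4000,
               samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Return the ``n`` genes with the largest log2(CPM+1) standard deviation.

    Computed across ``samples`` (default: all columns, the caller usually
    passes the OA samples).  Ties are broken by gene-id lexicographic order
    so the selection is deterministic; gene order in the output follows the
    input matrix.
    """
    if n > expr.shape[0]:
        raise ValidationError(f"requested {n} HVGs from {expr.shape[0]} genes")
    cols = list(samples) if samples is not None else list(expr.columns)
    sd = log2cpm(expr[cols]).std(axis=1, ddof=1)
    ranking = pd.DataFrame({"sd": sd, "gene": sd.index}).sort_values(
        ["sd", "gene"], ascending=[False, True], kind="stable")
    chosen = set(ranking.index[:n])
    return expr.loc[[g for g in expr.index if g in chosen]]


def run_qc(counts: pd.DataFrame, meta: pd.DataFrame, *,
           depth_low: int = DEPTH_LOW, depth_high: int = DEPTH_HIGH,
           control_max_variance: float = 3.0, min_cpm: float = 5.0,
           min_samples: int = 15) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full cartilage QC: depth window -> CPM -> control-variance filter ->
    minimum-expression filter.  Returns (cpm_oa, cpm_controls) on the
    surviving gene set; CPM is computed once and not re-normalized after
    gene filtering.
    """
    kept = filter_samples_by_depth(counts, depth_low, depth_high)
    expr = cpm(kept)
    meta_idx = meta.set_index("sample_id")
    status = meta_idx.loc[expr.columns, "status"]
    controls = status.index[status == "control"].tolist()
    oa = status.index[status == "OA"].tolist()
    if len(controls) >= 2:
        expr = filter_genes_control_variance(expr, controls, control_max_variance)
    expr = filter_genes_min_expression(expr, oa, min_cpm, min_samples)
    return expr[oa], expr[controls]
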