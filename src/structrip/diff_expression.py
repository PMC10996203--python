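"""Differential-expression thresholding and gene-set overlap.

Counts are normalized with median-of-ratios size factors.  The per-gene test
is a deliberately simple, exactly specified stand-in: a two-sided Fisher's
exact test on pooled-by-condition counts against pooled library totals, BH
FDR control, and the threshold rule fold change >= 2 (up) or <= 0.5 (down)
at FDR < 0.05.  It is not a negative-binomial GLM and is labeled as such in
outputs; on synthetic data it has an exact oracle, which is the point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment_stats import OverlapResult, bh_adjust, hypergeometric_overlap

EPS_MEAN = 0.5  # pseudo normalized-count mean for fold-change stability


class NormalizationError(ValueError):
    """No gene has nonzero counts in every library."""


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    factor_j = median over all-nonzero genes g of count_gj / geomean_g.
    """
    counts = matrix.to_numpy(dtype=float)
    nonzero = (counts > 0).all(axis=1)
    if not nonzero.any():
        raise NormalizationError(
            "no gene has nonzero counts in all libraries; consider pseudocounts"
        )
    sub = counts[nonzero]
    log_geomean = np.mean(np.log(sub), axis=1)
    ratios = np.exp(np.log(sub) - log_geomean[:, None])
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def _condition_of(lib: str) -> str:
    return lib.rsplit("_", 1)[0]


def test_de(matrix: pd.DataFrame, condition_a: str, condition_b: str,
            fc_cut: float = 2.0, fdr_cut: float = 0.05,
            eps: float = EPS_MEAN) -> pd.DataFrame:
    """Per-gene differential expression between two conditions (A vs B).

    Columns of ``matrix`` are ``<condition>_<replicate>``.  FC is the ratio of
    mean normalized counts (A over B, with pseudo-mean eps); p is two-sided
    Fisher's exact on pooled raw counts vs pooled library totals; FDR is BH.
    Direction: up iff FC >= fc_cut and FDR < fdr_cut; down iff FC <= 1/fc_cut
    and FDR < fdr_cut; ns otherwise.
    """
    conds = {lib: _condition_of(lib) for lib in matrix.columns}
    libs_a = [l for l in matrix.columns if conds[l] == condition_a]
    libs_b = [l for l in matrix.columns if conds[l] == condition_b]
    if not libs_a:
        raise KeyError(f"condition {condition_a!r} absent from the matrix")
    if not libs_b:
        raise KeyError(f"condition {condition_b!r} absent from the matrix")

    factors = size_factors(matrix[libs_a + libs_b])
    norm = matrix[libs_a + libs_b].div(factors, axis=1)
    mean_a = norm[libs_a].mean(axis=1)
    mean_b = norm[libs_b].mean(axis=1)
    fc = (mean_a + eps) / (mean_b + eps)

    pooled_a = matrix[libs_a].sum(axis=1).to_numpy()
    pooled_b = matrix[libs_b].sum(axis=1).to_numpy()
    total_a = int(pooled_a.sum())
    total_b = int(pooled_b.sum())
    pvals = np.ones(len(matrix))
    for i, (ca, cb) in enumerate(zip(pooled_a, pooled_b)):
        if ca == 0 and cb == 0:
            continue
        _, pvals[i] = stats.fisher_exact(
            [[int(ca), total_a - int(ca)], [int(cb), total_b - int(cb)]],
            alternative="two-sided",
        )
    fdr = bh_adjust(pvals)
    direction = np.where(
        (fc >= fc_cut) & (fdr < fdr_cut), "up",
        np.where((fc <= 1 / fc_cut) & (fdr < fdr_cut), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "gene_id": matrix.index,
            "log2_fc": np.log2(fc),
            "p": pvals,
            "fdr": fdr,
            "direction": direction,
        }
    ).set_index("gene_id")


def deg_overlap(deg: pd.DataFrame, other: Set | pd.DataFrame,
                universe: Set) -> Tuple[OverlapResult, Dict[str, int]]:
    """Overlap of a DEG set with a bound-gene set (or a second DEG table).

    Returns the hypergeometric overlap of the significant genes plus a signed
    breakdown (up & up, down & down) when both inputs carry direction.
    """
    deg_sig = set(deg.index[deg["direction"] != "ns"])
    if isinstance(other, pd.DataFrame):
        other_sig = set(other.index[other["direction"] != "ns"])
        breakdown = {
            "up_up": len(
                set(deg.index[deg["direction"] == "up"])
                & set(other.index[other["direction"] == "up"])
            ),
            "down_down": len(
                set(deg.index[deg["direction"] == "down"])
                & set(other.index[other["direction"] == "down"])
            ),
        }
    else:
        other_sig = set(other)
        breakdown = {
            "up": len(set(deg.index[deg["direction"] == "up"]) & other_sig),
            "down": len(set(deg.index[deg["direction"] == "down"]) & other_sig),
        }
    result = hypergeometric_overlap(deg_sig, other_sig, universe)
    return result, breakdown
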