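"""Tissue-specificity scoring by Shannon entropy and gene-set calling.

For a gene with non-negative expression e_t across T tissues, the relative
expression is p_t = e_t / sum(e), the overall entropy is

    H = -sum_t p_t * log2(p_t)      (bits, 0*log0 = 0)

and the categorical entropy for tissue t is

    Q_t = H - log2(p_t).

Low H means expression is concentrated in few tissues; low Q_t additionally
requires that tissue t carries a large share, so Q_t scores specificity *to*
t.  Q_t >= H always, with equality exactly when p_t = 1.

Tissue-specific genes are called by absolute cutoffs (H < 5 bits and
Q_target < 9 bits by default); a z-score mode (z_Q > 2, i.e. Q_target more
than two standard deviations below the across-gene mean) is also provided.
Housekeeping genes must show high overall entropy in two independent
expression datasets simultaneously.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("hmboost")

__all__ = [
    "ingest_expression",
    "relative_expression",
    "overall_entropy",
    "categorical_entropy",
    "score_specificity",
    "call_specific",
    "call_housekeeping",
]

#: microarray-style intensity floor applied before proportions
EXPRESSION_FLOOR = 1.0


def ingest_expression(df: pd.DataFrame, floor: float = EXPRESSION_FLOOR) -> pd.DataFrame:
    """Clip values below ``floor`` and drop genes with zero total expression.

    Clipping emulates the detection floor of microarray intensities and
    removes negative/zero pathologies before proportions are formed.
    """
    clean = df.clip(lower=floor)
    keep = clean.sum(axis=1) > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("ingest_expression: dropped %d all-zero gene(s)", dropped)
    return clean.loc[keep]


def relative_expression(row: np.ndarray) -> np.ndarray:
    """Per-tissue proportions p_t = e_t / sum(e) for one gene."""
    row = np.asarray(row, dtype=float)
    if np.any(row < 0):
        raise ValueError("expression values must be non-negative")
    total = row.sum()
    if total <= 0:
        raise ValueError("all-zero expression row: specificity undefined")
    return row / total


def overall_entropy(p: np.ndarray) -> float:
    """Shannon entropy of a proportion vector, in bits (0*log0 = 0)."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def categorical_entropy(p: np.ndarray, H: float, t: int) -> float:
    """Q_t = H - log2(p_t); +inf when the gene is silent in tissue t."""
    pt = float(np.asarray(p, dtype=float)[t])
    if pt <= 0:
        return float("inf")
    return H - float(np.log2(pt))


def score_specificity(expr: pd.DataFrame, target_tissue: str) -> pd.DataFrame:
    """Per-gene H, Q_target and z_Q for one ingested expression matrix.

    z_Q is oriented so that *high* z_Q means specific: z_Q = (mean(Q) - Q)/sd(Q),
    computed across genes with finite Q.
    """
    if target_tissue not in expr.columns:
        raise KeyError(f"target tissue {target_tissue!r} not in expression matrix")
    t = list(expr.columns).index(target_tissue)
    values = expr.to_numpy(dtype=float)
    totals = values.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("ingest_expression must remove all-zero genes first")
    p = values / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        H = -np.nansum(np.where(p > 0, p * np.log2(p), 0.0), axis=1)
        Q = np.where(p[:, t] > 0, H - np.log2(p[:, t]), np.inf)
    finite = np.isfinite(Q)
    if finite.sum() >= 2 and np.std(Q[finite]) > 0:
        z = np.full(len(Q), -np.inf)
        z[finite] = (Q[finite].mean() - Q[finite]) / Q[finite].std(ddof=0)
    else:
        z = np.zeros(len(Q))
    return pd.DataFrame({"H": H, "Q_target": Q, "z_Q": z}, index=expr.index)


def call_specific(
    scores: pd.DataFrame,
    h_max: float = 5.0,
    q_max: float = 9.0,
    mode: str = "absolute",
    z_min: float = 2.0,
) -> set[str]:
    """Genes specific to the scored target tissue.

    ``mode="absolute"`` (default): H < h_max and Q_target < q_max.
    ``mode="zscore"``: H < h_max and z_Q > z_min.
    """
    if mode == "absolute":
        mask = (scores["H"] < h_max) & (scores["Q_target"] < q_max)
    elif mode == "zscore":
        mask = (scores["H"] < h_max) & (scores["z_Q"] > z_min)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return set(scores.index[mask])


def call_housekeeping(
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    h_min_a: float = 6.2,
    h_min_b: float = 8.9,
) -> set[str]:
    """Genes broadly expressed in both datasets (H above both floors).

    The call is made on the intersection of the two gene universes.
    """
    shared = scores_a.index.intersection(scores_b.index)
    if len(shared) == 0:
        raise ValueError("expression datasets share no genes")
    a = scores_a.loc[shared, "H"]
    b = scores_b.loc[shared, "H"]
    return set(shared[(a > h_min_a) & (b > h_min_b)])
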