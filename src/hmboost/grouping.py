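"""Partition histone marks into Set I / Set II by PCA of TSS-proximal signal.

The gene x mark matrix of tag sums in the +/-2 kb TSS window is
column-standardized and decomposed by PCA.  Set I collects the marks with
the highest contributions to the first ``n_components`` principal
components; Set II is the remainder.  "Highest contribution" defaults to an
absolute loading above 1/sqrt(M) (above-average contribution for M marks);
a top-k-per-component rule is available as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core import GeneModel, TagTrack
from .features import _count_relative

logger = logging.getLogger("hmboost")

__all__ = ["MarkPartition", "mark_matrix", "split_sets"]


@dataclass
class MarkPartition:
    set_I: list[str]
    set_II: list[str]
    loadings: pd.DataFrame          # marks x components
    variance_explained: np.ndarray  # per retained component
    excluded: list[str] = field(default_factory=list)  # constant columns

    def __post_init__(self) -> None:
        if set(self.set_I) & set(self.set_II):
            raise ValueError("Set I and Set II overlap")
        ve = np.asarray(self.variance_explained)
        if np.any(np.diff(ve) > 1e-9) or ve.sum() > 1 + 1e-9:
            raise ValueError("variance_explained must be non-increasing, sum <= 1")

    def to_dict(self) -> dict:
        return {
            "set_I": self.set_I,
            "set_II": self.set_II,
            "variance_explained": [float(v) for v in self.variance_explained],
            "loadings": {
                m: [float(v) for v in row]
                for m, row in self.loadings.iterrows()
            },
            "excluded": self.excluded,
        }


def mark_matrix(
    genes: list[GeneModel],
    tracks: list[TagTrack],
    halfwidth: int = 2000,
) -> pd.DataFrame:
    """Gene x mark matrix of tag counts in the TSS +/- ``halfwidth`` window."""
    tracks = sorted(tracks, key=lambda t: t.mark_name)
    cols = {
        t.mark_name: np.array(
            [_count_relative(t, g, -halfwidth, halfwidth) for g in genes],
            dtype=float,
        )
        for t in tracks
    }
    return pd.DataFrame(cols, index=[g.id for g in genes])


def split_sets(
    matrix: pd.DataFrame,
    n_components: int = 4,
    rule: str = "loading",
    top_k: int = 3,
) -> MarkPartition:
    """PCA over standardized mark columns; assign marks to Set I / Set II.

    ``rule="loading"``: Set I = marks whose |loading| on any of the first
    ``n_components`` components is at least 1/sqrt(M) (an above-average
    contribution among M marks).
    ``rule="top_k"``: Set I = union of the ``top_k`` |loading| marks per
    component.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    marks = list(matrix.columns)
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=0)
    constant = [m for m, s in zip(marks, sd) if s == 0]
    if constant:
        logger.warning("split_sets: constant mark column(s) %s excluded from "
                       "PCA, assigned to Set II", ",".join(constant))
    active = [m for m in marks if m not in constant]
    if len(active) < n_components:
        raise ValueError("fewer varying marks than requested components")
    sub = matrix[active].to_numpy(dtype=float)
    z = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=0)
    n_components = min(n_components, min(z.shape))
    pca = PCA(n_components=min(len(active), z.shape[0] - 1), svd_solver="full")
    pca.fit(z)
    loadings = pd.DataFrame(
        pca.components_.T,
        index=active,
        columns=[f"PC{i+1}" for i in range(pca.components_.shape[0])],
    )
    lead = loadings.iloc[:, :n_components].abs()
    if rule == "loading":
        cut = 1.0 / np.sqrt(len(active))
        chosen = set(lead.index[(lead >= cut - 1e-12).any(axis=1)])
    elif rule == "top_k":
        chosen = set()
        for col in lead.columns:
            chosen |= set(lead[col].nlargest(top_k).index)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    set_I = [m for m in marks if m in chosen]
    set_II = [m for m in marks if m not in chosen]
    return MarkPartition(
        set_I=set_I,
        set_II=set_II,
        loadings=loadings,
        variance_explained=pca.explained_variance_ratio_.copy(),
        excluded=constant,
    )
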