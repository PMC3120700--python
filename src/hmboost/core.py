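"""Core data containers shared across the pipeline.

Coordinates are 1-based closed genomic positions throughout the package;
BED input (0-based half-open) is converted on ingest by :mod:`hmboost.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["GeneModel", "TagTrack", "FeatureTable", "Stump", "BoostModel"]


@dataclass(frozen=True)
class GeneModel:
    """A transcript anchored at its TSS.

    Exons are (start, end) 1-based closed genomic intervals ordered 5'->3'
    in transcript orientation: for a minus-strand gene the first exon is the
    one with the highest genomic coordinates.
    """

    id: str
    chrom: str
    strand: str
    tss: int
    exons: tuple[tuple[int, int], ...]
    cpg_related: bool | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.id}: at least one exon required")
        for s, e in self.exons:
            if s > e or s < 1:
                raise ValueError(f"gene {self.id}: bad exon ({s},{e})")
        genomic = sorted(self.exons)
        for (_, e1), (s2, _) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise ValueError(f"gene {self.id}: overlapping exons")
        # transcript orientation: ascending starts on +, descending on -
        expect = genomic if self.strand == "+" else genomic[::-1]
        if tuple(expect) != tuple(self.exons):
            raise ValueError(f"gene {self.id}: exons not in transcript order")
        five_prime = genomic[0][0] if self.strand == "+" else genomic[-1][1]
        if self.tss != five_prime:
            raise ValueError(
                f"gene {self.id}: tss {self.tss} is not the transcript 5' end "
                f"({five_prime})"
            )

    @property
    def body_span(self) -> tuple[int, int]:
        """Genomic (start, end) of the whole transcript body."""
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)

    @property
    def body_length(self) -> int:
        s, e = self.body_span
        return e - s + 1


@dataclass
class TagTrack:
    """Sequencing-tag anchor positions for one histone mark.

    ``tags`` maps chromosome -> sorted int array of 1-based anchor
    coordinates (one anchor per sequenced tag).
    """

    mark_name: str
    tags: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for chrom, pos in self.tags.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.size and arr.min() < 1:
                raise ValueError(
                    f"track {self.mark_name}: non-positive coordinate on {chrom}"
                )
            if arr.size and np.any(np.diff(arr) < 0):
                arr = np.sort(arr)
            clean[chrom] = arr
        self.tags = clean

    @property
    def total_tag_count(self) -> int:
        return int(sum(arr.size for arr in self.tags.values()))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of anchors on ``chrom`` within [start, end] (closed)."""
        arr = self.tags.get(chrom)
        if arr is None or arr.size == 0:
            return 0
        lo = np.searchsorted(arr, start, side="left")
        hi = np.searchsorted(arr, end, side="right")
        return int(hi - lo)


@dataclass
class FeatureTable:
    """Gene x feature matrix with structured feature names.

    Feature names are ``mark:region`` strings, e.g. ``H3K4me3:+1`` for a
    promoter nucleosome or ``H3K4me3:body_sum`` for a gene-body statistic.
    """

    data: pd.DataFrame
    region_kind: str = "promoter"

    def __post_init__(self) -> None:
        if self.region_kind not in ("promoter", "body", "control"):
            raise ValueError(f"unknown region_kind {self.region_kind!r}")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate feature names")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    @property
    def marks(self) -> list[str]:
        seen: dict[str, None] = {}
        for name in self.data.columns:
            seen.setdefault(name.split(":", 1)[0])
        return list(seen)

    def restrict_genes(self, genes: Iterable[str]) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(genes)], self.region_kind)


@dataclass(frozen=True)
class Stump:
    """One-split decision tree: predict ``polarity`` where value > threshold."""

    feature: str
    threshold: float
    polarity: int  # +1 or -1: the label predicted on the > side
    weighted_error: float
    weight: float  # alpha

    def decide(self, x: np.ndarray) -> np.ndarray:
        return np.where(x > self.threshold, self.polarity, -self.polarity)


@dataclass
class BoostModel:
    """Ordered weighted stumps from boosting, with training bookkeeping."""

    stumps: list[Stump]
    feature_names: list[str]
    rounds_trained: int = 0

    def __post_init__(self) -> None:
        if self.rounds_trained == 0:
            self.rounds_trained = len(self.stumps)
        if self.rounds_trained != len(self.stumps):
            raise ValueError("rounds_trained must equal number of stumps")
        known = set(self.feature_names)
        for st in self.stumps:
            if st.feature not in known:
                raise ValueError(f"stump feature {st.feature!r} not in training columns")

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "rounds_trained": self.rounds_trained,
            "stumps": [
                {
                    "feature": s.feature,
                    "threshold": s.threshold,
                    "polarity": s.polarity,
                    "weighted_error": s.weighted_error,
                    "weight": s.weight,
                }
                for s in self.stumps
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BoostModel":
        stumps = [
            Stump(
                feature=s["feature"],
                threshold=float(s["threshold"]),
                polarity=int(s["polarity"]),
                weighted_error=float(s["weighted_error"]),
                weight=float(s["weight"]),
            )
            for s in d["stumps"]
        ]
        return cls(
            stumps=stumps,
            feature_names=list(d["feature_names"]),
            rounds_trained=int(d["rounds_trained"]),
        )
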