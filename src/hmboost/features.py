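"""Nucleosome-anchored feature tables for promoter, gene-body and control regions.

The promoter is a fixed grid of 26 TSS-relative nucleosome intervals, from
the 6th nucleosome upstream to the 20th downstream.  The -2..+5 intervals use
published nucleosome positions around the TSS:

    -2 [-370,-196]  -1 [-195,-46]  +1 [-45,134]  +2 [135,314]
    +3 [315,494]    +4 [495,674]   +5 [675,859]

and every interval beyond these anchors extends 150 bp from its inner
neighbour.  Relative coordinates are transcript-oriented: on the minus strand
"downstream" still means the direction of transcription.  The HMV level of a
mark on a nucleosome is the number of tag anchors falling in the interval.

Gene-body features per mark: sum and per-bp average over the first exon, the
first intron and the whole gene body, plus the summed count over the first
twenty 150-bp windows tiled downstream of the first exon's 3' end (windows
running past the transcript end are truncated).

Control regions repeat the promoter featurization with the anchor moved
50 kb transcript-upstream of the TSS, providing a null baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FeatureTable, GeneModel, TagTrack

logger = logging.getLogger("hmboost")

__all__ = [
    "NucleosomeGrid",
    "nucleosome_grid",
    "to_relative",
    "classify_cpg",
    "promoter_features",
    "body_features",
    "control_features",
    "regional_signal_density",
]

# printed anchor nucleosome positions, TSS-relative closed intervals
_ANCHORS = {
    -2: (-370, -196),
    -1: (-195, -46),
    1: (-45, 134),
    2: (135, 314),
    3: (315, 494),
    4: (495, 674),
    5: (675, 859),
}

_BODY_STATS = ("first_exon_sum", "first_exon_avg", "first_intron_sum",
               "first_intron_avg", "body_sum", "body_avg", "post_exon1_nuc_sum")


@dataclass(frozen=True)
class NucleosomeGrid:
    """Ordered TSS-relative nucleosome intervals, indexed -u..-1, +1..+d."""

    indices: tuple[int, ...]
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.indices) != len(self.intervals):
            raise ValueError("indices/intervals length mismatch")

    def __len__(self) -> int:
        return len(self.indices)

    def interval(self, index: int) -> tuple[int, int]:
        return self.intervals[self.indices.index(index)]

    @property
    def span(self) -> tuple[int, int]:
        return self.intervals[0][0], self.intervals[-1][1]


def nucleosome_grid(upstream: int = 6, downstream: int = 20) -> NucleosomeGrid:
    """Build the promoter nucleosome grid (-upstream .. +downstream).

    The default -6..+20 yields 26 intervals; -6..+9 is the alternate
    promoter extent.
    """
    if upstream < 2 or downstream < 5:
        raise ValueError("grid must include the anchor nucleosomes -2..+5")
    items: list[tuple[int, tuple[int, int]]] = []
    for k in range(-upstream, 0):
        if k in _ANCHORS:
            items.append((k, _ANCHORS[k]))
        else:  # extend 150 bp outward from the inner neighbour
            inner_start = _ANCHORS[-2][0]
            end = inner_start - 1 - 150 * (-k - 3)
            items.append((k, (end - 149, end)))
    for k in range(1, downstream + 1):
        if k in _ANCHORS:
            items.append((k, _ANCHORS[k]))
        else:
            outer = _ANCHORS[5][1]
            start = outer + 1 + 150 * (k - 6)
            items.append((k, (start, start + 149)))
    items.sort(key=lambda kv: kv[1][0])
    return NucleosomeGrid(
        indices=tuple(k for k, _ in items),
        intervals=tuple(iv for _, iv in items),
    )


def to_relative(pos: int, gene: GeneModel) -> int:
    """Genomic position -> transcript-oriented TSS-relative coordinate."""
    return pos - gene.tss if gene.strand == "+" else gene.tss - pos


def _count_relative(track: TagTrack, gene: GeneModel, rel_lo: int, rel_hi: int,
                    anchor: int | None = None) -> int:
    """Count anchors whose relative coordinate (to ``anchor``, default the
    TSS) lies in [rel_lo, rel_hi]."""
    a = gene.tss if anchor is None else anchor
    if gene.strand == "+":
        lo, hi = a + rel_lo, a + rel_hi
    else:
        lo, hi = a - rel_hi, a - rel_lo
    return track.count_in(gene.chrom, lo, hi)


def classify_cpg(
    gene: GeneModel,
    cpg_islands: dict[str, np.ndarray],
    upstream: int = 2000,
    downstream: int = 500,
) -> bool:
    """True iff a CpG island overlaps the strand-aware window
    [-upstream, +downstream] around the TSS."""
    islands = cpg_islands.get(gene.chrom)
    if islands is None or len(islands) == 0:
        return False
    if gene.strand == "+":
        lo, hi = gene.tss - upstream, gene.tss + downstream
    else:
        lo, hi = gene.tss - downstream, gene.tss + upstream
    return bool(np.any((islands[:, 0] <= hi) & (islands[:, 1] >= lo)))


def _warn_missing_chroms(genes: list[GeneModel], tracks: list[TagTrack]) -> None:
    chroms = {g.chrom for g in genes}
    for track in tracks:
        missing = chroms - set(track.tags)
        if missing:
            logger.warning(
                "track %s has no tags on chromosome(s) %s; zero counts used",
                track.mark_name, ",".join(sorted(missing)),
            )


def promoter_features(
    genes: list[GeneModel],
    tracks: list[TagTrack],
    grid: NucleosomeGrid | None = None,
    region_kind: str = "promoter",
    anchors: dict[str, int] | None = None,
) -> FeatureTable:
    """Per-gene HMV level on every grid nucleosome, one column per
    (mark, nucleosome index); marks alphabetical, index ascending."""
    if grid is None:
        grid = nucleosome_grid()
    _warn_missing_chroms(genes, tracks)
    tracks = sorted(tracks, key=lambda t: t.mark_name)
    cols: dict[str, np.ndarray] = {}
    for track in tracks:
        for idx, (lo, hi) in zip(grid.indices, grid.intervals):
            name = f"{track.mark_name}:{idx:+d}"
            cols[name] = np.array(
                [
                    _count_relative(
                        track, g, lo, hi,
                        anchor=None if anchors is None else anchors[g.id],
                    )
                    for g in genes
                ],
                dtype=float,
            )
    df = pd.DataFrame(cols, index=[g.id for g in genes], dtype=float)
    return FeatureTable(df, region_kind=region_kind)


def _first_intron(gene: GeneModel) -> tuple[int, int] | None:
    """Genomic (start, end) of the first intron in transcript orientation."""
    if len(gene.exons) < 2:
        return None
    e1, e2 = gene.exons[0], gene.exons[1]
    if gene.strand == "+":
        return e1[1] + 1, e2[0] - 1
    return e2[1] + 1, e1[0] - 1


def _post_exon1_region(gene: GeneModel, n_windows: int = 20, width: int = 150
                       ) -> tuple[int, int] | None:
    """Genomic span of ``n_windows`` windows tiled transcript-downstream from
    the first exon's 3' end, truncated at the transcript end."""
    body_lo, body_hi = gene.body_span
    extent = n_windows * width
    if gene.strand == "+":
        start = gene.exons[0][1] + 1
        end = min(start + extent - 1, body_hi)
        if start > body_hi:
            return None
        return start, end
    end = gene.exons[0][0] - 1
    start = max(end - extent + 1, body_lo)
    if end < body_lo:
        return None
    return start, end


def body_features(
    genes: list[GeneModel],
    tracks: list[TagTrack],
    grid: NucleosomeGrid | None = None,
) -> FeatureTable:
    """Gene-body statistics per mark; averages are per-bp densities."""
    _warn_missing_chroms(genes, tracks)
    tracks = sorted(tracks, key=lambda t: t.mark_name)
    index = [g.id for g in genes]
    cols: dict[str, list[float]] = {
        f"{t.mark_name}:{stat}": [] for t in tracks for stat in _BODY_STATS
    }
    intronless = []
    for g in genes:
        body = g.body_span
        exon1 = g.exons[0]
        intron1 = _first_intron(g)
        post = _post_exon1_region(g)
        if intron1 is None:
            intronless.append(g.id)
        for t in tracks:
            e_sum = t.count_in(g.chrom, *exon1)
            b_sum = t.count_in(g.chrom, *body)
            i_sum = t.count_in(g.chrom, *intron1) if intron1 else 0
            p_sum = t.count_in(g.chrom, *post) if post else 0
            cols[f"{t.mark_name}:first_exon_sum"].append(e_sum)
            cols[f"{t.mark_name}:first_exon_avg"].append(
                e_sum / (exon1[1] - exon1[0] + 1)
            )
            cols[f"{t.mark_name}:first_intron_sum"].append(i_sum)
            cols[f"{t.mark_name}:first_intron_avg"].append(
                i_sum / (intron1[1] - intron1[0] + 1) if intron1 else 0.0
            )
            cols[f"{t.mark_name}:body_sum"].append(b_sum)
            cols[f"{t.mark_name}:body_avg"].append(b_sum / g.body_length)
            cols[f"{t.mark_name}:post_exon1_nuc_sum"].append(p_sum)
    if intronless:
        logger.info("body_features: %d intronless gene(s): first-intron "
                    "features set to 0", len(intronless))
    df = pd.DataFrame(cols, index=index, dtype=float)
    df.attrs["intronless"] = intronless
    return FeatureTable(df, region_kind="body")


def control_features(
    genes: list[GeneModel],
    tracks: list[TagTrack],
    grid: NucleosomeGrid | None = None,
    offset: int = 50_000,
) -> FeatureTable:
    """Promoter featurization re-anchored ``offset`` bp transcript-upstream.

    Genes whose control anchor would fall off the chromosome start are
    dropped with a warning.
    """
    if grid is None:
        grid = nucleosome_grid()
    anchors: dict[str, int] = {}
    kept: list[GeneModel] = []
    extent_up = -grid.span[0]
    for g in genes:
        a = g.tss - offset if g.strand == "+" else g.tss + offset
        if a - extent_up < 1:
            logger.warning("control_features: dropping %s (anchor %d too close "
                           "to chromosome start)", g.id, a)
            continue
        anchors[g.id] = a
        kept.append(g)
    return promoter_features(kept, tracks, grid, region_kind="control",
                             anchors=anchors)


def regional_signal_density(
    gene: GeneModel,
    track: TagTrack,
    region: str = "body",
    expression: float | None = None,
) -> float:
    """Length-controlled tag density in exonic/intronic/whole-body regions,
    optionally further divided by an expression level."""
    if region == "body":
        spans = [gene.body_span]
    elif region == "exonic":
        spans = list(gene.exons)
    elif region == "intronic":
        genomic = sorted(gene.exons)
        spans = [
            (e1[1] + 1, s2[0] - 1)
            for e1, s2 in zip(genomic, genomic[1:])
            if s2[0] - 1 >= e1[1] + 1
        ]
    else:
        raise ValueError(f"unknown region {region!r}")
    length = sum(b - a + 1 for a, b in spans)
    if length <= 0:
        raise ValueError(f"gene {gene.id}: zero-length {region} region")
    count = sum(track.count_in(gene.chrom, a, b) for a, b in spans)
    dens = count / length
    if expression is not None:
        dens /= expression
    return dens
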