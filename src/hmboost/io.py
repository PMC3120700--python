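"""Readers, writers and run configuration.

BED input is read in the standard 0-based half-open dialect and converted to
the package's internal 1-based closed coordinates on ingest.  Each
sequenced-tag interval is reduced to a single anchor coordinate — by default
its midpoint, which is robust to unknown read length; 5' -end anchoring is
available via ``anchor="five_prime"``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import BoostModel, FeatureTable, GeneModel, TagTrack

logger = logging.getLogger("hmboost")

__all__ = [
    "RunConfig",
    "read_config",
    "write_config",
    "read_gene_models",
    "write_gene_models",
    "read_tag_track",
    "write_tag_track",
    "read_bed_intervals",
    "read_feature_table",
    "write_feature_table",
    "read_expression",
    "write_expression",
    "save_model",
    "load_model",
]


class ParseError(ValueError):
    """Malformed record in an input file; message names the line number."""


@dataclass
class RunConfig:
    """Run-wide parameters; serializable to a YAML key-value file."""

    seed: int = 0
    h_max_specific: float = 5.0       # overall-entropy cutoff for specific call (bits)
    q_max_specific: float = 9.0       # categorical-entropy cutoff (bits)
    h_min_housekeeping_a: float = 6.2  # dataset-A overall-entropy floor (bits)
    h_min_housekeeping_b: float = 8.9  # dataset-B overall-entropy floor (bits)
    upstream_nucleosomes: int = 6
    downstream_nucleosomes: int = 20
    rounds: int = 100                 # boosting rounds
    replicates: int = 100             # balanced-resampling replicates
    folds: int = 5
    control_offset: int = 50_000      # bp upstream of the TSS for control regions

    def __post_init__(self) -> None:
        for name in (
            "upstream_nucleosomes",
            "downstream_nucleosomes",
            "rounds",
            "replicates",
            "folds",
            "control_offset",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # the control window must not overlap the promoter window: the
        # offset has to exceed the full grid span around the TSS
        from .features import nucleosome_grid

        span = nucleosome_grid(self.upstream_nucleosomes,
                               self.downstream_nucleosomes).span
        if self.control_offset <= span[1] - span[0]:
            raise ValueError("control_offset must exceed the promoter extent")


def write_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))


def read_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def _gene_from_bed12(fields: list[str], lineno: int) -> GeneModel:
    try:
        chrom = fields[0]
        start0, end0 = int(fields[1]), int(fields[2])
        name = fields[3]
        strand = fields[5]
        block_count = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
    except (IndexError, ValueError) as exc:
        raise ParseError(f"line {lineno}: malformed BED12 record ({exc})") from None
    if len(sizes) != block_count or len(offsets) != block_count:
        raise ParseError(f"line {lineno}: blockCount does not match block lists")
    if start0 < 0:
        raise ParseError(f"line {lineno}: negative chromStart")
    exons = [
        (start0 + off + 1, start0 + off + size)  # 0-based half-open -> 1-based closed
        for off, size in zip(offsets, sizes)
    ]
    if strand == "-":
        exons = exons[::-1]
        tss = end0
    else:
        tss = start0 + 1
    return GeneModel(id=name, chrom=chrom, strand=strand, tss=tss, exons=tuple(exons))


def _genes_from_gtf(path: Path) -> list[GeneModel]:
    by_tx: dict[str, dict] = {}
    order: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise ParseError(f"line {lineno}: GTF record has {len(fields)} fields")
        if fields[2] != "exon":
            continue
        try:
            start, end = int(fields[3]), int(fields[4])  # GTF is already 1-based closed
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer coordinates") from None
        attrs = dict(
            part.strip().split(" ", 1)
            for part in fields[8].rstrip(";").split(";")
            if part.strip()
        )
        tx = attrs.get("transcript_id", "").strip('"')
        if not tx:
            raise ParseError(f"line {lineno}: missing transcript_id")
        rec = by_tx.setdefault(tx, {"chrom": fields[0], "strand": fields[6], "exons": []})
        rec["exons"].append((start, end))
        if tx not in rec:
            pass
        if len(rec["exons"]) == 1:
            order.append(tx)
    genes = []
    for tx in order:
        rec = by_tx[tx]
        exons = sorted(rec["exons"])
        if rec["strand"] == "-":
            exons = exons[::-1]
            tss = exons[0][1]
        else:
            tss = exons[0][0]
        genes.append(
            GeneModel(id=tx, chrom=rec["chrom"], strand=rec["strand"], tss=tss,
                      exons=tuple(exons))
        )
    return genes


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read transcripts from BED12 (default) or GTF (.gtf/.gff suffix)."""
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        genes = _genes_from_gtf(path)
    else:
        genes = []
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            genes.append(_gene_from_bed12(line.split("\t"), lineno))
    if not genes:
        raise ParseError(f"{path}: no transcript records found")
    return genes


def write_gene_models(genes: list[GeneModel], path: str | Path) -> None:
    """Write transcripts as BED12 (inverse of :func:`read_gene_models`)."""
    lines = []
    for g in genes:
        genomic = sorted(g.exons)
        start0 = genomic[0][0] - 1
        end0 = genomic[-1][1]
        sizes = ",".join(str(e - s + 1) for s, e in genomic)
        offsets = ",".join(str(s - 1 - start0) for s, _ in genomic)
        lines.append(
            "\t".join(
                [
                    g.chrom,
                    str(start0),
                    str(end0),
                    g.id,
                    "0",
                    g.strand,
                    str(start0),
                    str(end0),
                    "0",
                    str(len(genomic)),
                    sizes,
                    offsets,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# tag tracks and plain intervals
# ---------------------------------------------------------------------------


def read_tag_track(
    path: str | Path, mark_name: str, anchor: str = "midpoint"
) -> TagTrack:
    """Read a BED tag file into a :class:`TagTrack` of anchor coordinates.

    ``anchor="midpoint"`` places each tag at the floor midpoint of its
    1-based closed interval; ``anchor="five_prime"`` uses the strand-aware
    5' end (interval start on '+', end on '-'; start when strand is absent).
    """
    if anchor not in ("midpoint", "five_prime"):
        raise ValueError(f"unknown anchor {anchor!r}")
    per_chrom: dict[str, list[int]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        try:
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
        except (IndexError, ValueError):
            raise ParseError(f"line {lineno}: malformed BED record") from None
        if start0 < 0 or end0 <= start0:
            raise ParseError(f"line {lineno}: bad interval [{start0},{end0})")
        start1, end1 = start0 + 1, end0
        if anchor == "midpoint":
            pos = (start1 + end1) // 2
        else:
            strand = fields[5] if len(fields) > 5 else "+"
            pos = end1 if strand == "-" else start1
        per_chrom.setdefault(chrom, []).append(pos)
    return TagTrack(
        mark_name=mark_name,
        tags={c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in per_chrom.items()},
    )


def write_tag_track(track: TagTrack, path: str | Path) -> None:
    """Write anchors as 1-bp BED intervals (round-trips under any anchor rule)."""
    lines = []
    for chrom in sorted(track.tags):
        for pos in track.tags[chrom]:
            lines.append(f"{chrom}\t{pos - 1}\t{pos}\t{track.mark_name}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed_intervals(path: str | Path) -> dict[str, np.ndarray]:
    """Read plain BED intervals (e.g. CpG islands) into per-chromosome
    (n, 2) arrays of 1-based closed [start, end]."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        try:
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
        except (IndexError, ValueError):
            raise ParseError(f"line {lineno}: malformed BED record") from None
        if start0 < 0 or end0 <= start0:
            raise ParseError(f"line {lineno}: bad interval [{start0},{end0})")
        per_chrom.setdefault(chrom, []).append((start0 + 1, end0))
    return {
        c: np.asarray(sorted(v), dtype=np.int64).reshape(-1, 2)
        for c, v in per_chrom.items()
    }


# ---------------------------------------------------------------------------
# tables and matrices
# ---------------------------------------------------------------------------


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = table.data.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_feature_table(path: str | Path, region_kind: str = "promoter") -> FeatureTable:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric or ragged feature table ({exc})") from None
    df.index = df.index.astype(str)
    return FeatureTable(df, region_kind=region_kind)


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df.astype(float)


def save_model(model: BoostModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def load_model(path: str | Path) -> BoostModel:
    return BoostModel.from_dict(json.loads(Path(path).read_text()))
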