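"""Synthetic benchmark generator with planted class structure.

The generator emulates the statistical shape of the real inputs so that
every pipeline stage is testable without downloads:

* two expression matrices (a tissue atlas of ~100 tissues and a larger
  ~677-sample survey) in which planted "specific" genes are expressed in a
  small block of target-adjacent tissues and planted "housekeeping" genes
  are expressed broadly, with entropies landing on the correct side of the
  calling thresholds by construction;
* a toy linear genome of non-overlapping, mixed-strand, mostly multi-exon
  gene models with CpG islands placed at a configurable fraction of TSSs;
* per-mark tag tracks where counts per (gene, mark, region) are negative
  binomial (ChIP-seq-like overdispersion) with the mean multiplied by a
  fold-change f at planted informative (mark, region) pairs for specific
  genes.  Marks in a redundancy group share one latent Bernoulli amplitude
  per gene, so their informative signal is correlated.

Everything is deterministic given the design seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import GeneModel, TagTrack
from .features import NucleosomeGrid, nucleosome_grid
from .io import (
    write_expression,
    write_gene_models,
    write_tag_track,
)

__all__ = [
    "SimulationDesign",
    "DEFAULT_MARKS",
    "simulate_expression",
    "simulate_genome",
    "simulate_tags",
    "make_dataset",
]

DEFAULT_MARKS = (
    "H2A.Z", "H3K27ac", "H3K27me3", "H3K36me3", "H3K4me1", "H3K4me2",
    "H3K4me3", "H3K79me2", "H3K79me3", "H3K9ac", "H3K9me1", "H4K20me1",
)

#: default planted informative (mark, region, fold-change) triples: the
#: marks reported as most predictive, raised at TSS-proximal nucleosomes and
#: the first exon of specific genes
DEFAULT_INFORMATIVE = (
    ("H3K4me3", "+1", 6.0),
    ("H3K4me3", "+2", 6.0),
    ("H3K4me3", "+3", 6.0),
    ("H3K27ac", "+1", 6.0),
    ("H3K27ac", "+2", 6.0),
    ("H3K79me3", "+2", 6.0),
    ("H3K79me3", "+3", 6.0),
    ("H3K4me3", "first_exon", 6.0),
    ("H3K27ac", "first_exon", 6.0),
)



@dataclass
class SimulationDesign:
    """Study-condition parameters for the synthetic benchmark."""

    n_specific: int = 454
    n_housekeeping: int = 630
    n_tissues_a: int = 100          # atlas-like dataset
    n_tissues_b: int = 677          # survey-like dataset
    specific_tissue_count: int = 8  # blood-cell-like expressing subset
    marks: tuple[str, ...] = DEFAULT_MARKS
    informative: tuple[tuple[str, str, float], ...] = DEFAULT_INFORMATIVE
    base_rate: float = 3.0          # expected tags per nucleosome-equivalent
    dispersion: float = 0.3         # NB overdispersion (0 -> Poisson)
    redundancy_groups: tuple[tuple[str, ...], ...] = ()
    multi_exon_fraction: float = 0.9
    cpg_fraction: float = 0.6
    gene_spacing: int = 80_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.specific_tissue_count >= min(self.n_tissues_a, self.n_tissues_b):
            raise ValueError("specific_tissue_count must be < n_tissues")
        for mark, region, f in self.informative:
            if mark not in self.marks:
                raise ValueError(f"informative mark {mark!r} not in marks")
            if f <= 1:
                raise ValueError("informative fold-change f must be > 1")
        for group in self.redundancy_groups:
            for mark in group:
                if mark not in self.marks:
                    raise ValueError(f"redundancy mark {mark!r} not in marks")

    @property
    def n_genes(self) -> int:
        return self.n_specific + self.n_housekeeping

    @property
    def target_tissue(self) -> str:
        return "tissue000"


def _gene_ids(design: SimulationDesign) -> list[str]:
    width = len(str(design.n_genes))
    return [f"gene{i:0{width}d}" for i in range(design.n_genes)]


def _labels(design: SimulationDesign) -> pd.Series:
    ids = _gene_ids(design)
    lab = ["specific"] * design.n_specific + ["housekeeping"] * design.n_housekeeping
    return pd.Series(lab, index=ids, name="label")


def _expression_matrix(
    design: SimulationDesign, n_tissues: int, rng: np.random.Generator
) -> pd.DataFrame:
    ids = _gene_ids(design)
    tissues = [f"tissue{i:03d}" for i in range(n_tissues)]
    values = rng.uniform(0.0, 1.0, size=(design.n_genes, n_tissues))
    k = design.specific_tissue_count
    # specific genes: strong expression confined to the first k tissues
    values[: design.n_specific, :k] = rng.lognormal(
        mean=np.log(500.0), sigma=0.5, size=(design.n_specific, k)
    )
    # housekeeping genes: broad lognormal expression everywhere
    values[design.n_specific:, :] = rng.lognormal(
        mean=np.log(100.0), sigma=0.4, size=(design.n_housekeeping, n_tissues)
    )
    return pd.DataFrame(values, index=ids, columns=tissues)


def simulate_expression(
    design: SimulationDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Two expression-dataset variants plus planted truth labels.

    Specific genes land below the H/Q specificity cutoffs in dataset A;
    housekeeping genes clear the overall-entropy floors in both datasets
    (near-uniform expression keeps H close to log2 T).
    """
    rng = np.random.default_rng([design.seed, 11])
    expr_a = _expression_matrix(design, design.n_tissues_a, rng)
    expr_b = _expression_matrix(design, design.n_tissues_b, rng)
    return expr_a, expr_b, _labels(design)


def simulate_genome(
    design: SimulationDesign,
) -> tuple[list[GeneModel], dict[str, np.ndarray], pd.Series]:
    """Non-overlapping toy gene models, CpG islands, and planted CpG flags."""
    rng = np.random.default_rng([design.seed, 23])
    ids = _gene_ids(design)
    genes: list[GeneModel] = []
    islands: list[tuple[int, int]] = []
    cpg_flags: list[bool] = []
    chrom = "chr1"
    for i, gid in enumerate(ids):
        tss = 100_000 + i * design.gene_spacing
        strand = "+" if rng.random() < 0.5 else "-"
        multi = rng.random() < design.multi_exon_fraction
        n_exons = int(rng.integers(2, 5)) if multi else 1
        exon_lens = rng.integers(200, 1200, size=n_exons)
        intron_lens = rng.integers(500, 3000, size=max(n_exons - 1, 0))
        # build exons walking downstream from the TSS
        exons: list[tuple[int, int]] = []
        pos = tss
        for j in range(n_exons):
            if strand == "+":
                exons.append((pos, pos + int(exon_lens[j]) - 1))
                pos = exons[-1][1] + 1
                if j < n_exons - 1:
                    pos += int(intron_lens[j])
            else:
                exons.append((pos - int(exon_lens[j]) + 1, pos))
                pos = exons[-1][0] - 1
                if j < n_exons - 1:
                    pos -= int(intron_lens[j])
        genes.append(
            GeneModel(id=gid, chrom=chrom, strand=strand, tss=tss,
                      exons=tuple(exons))
        )
        has_cpg = rng.random() < design.cpg_fraction
        cpg_flags.append(has_cpg)
        if has_cpg:
            islands.append((tss - 200, tss + 200))
    cpg = {chrom: np.asarray(sorted(islands), dtype=np.int64).reshape(-1, 2)}
    return genes, cpg, pd.Series(cpg_flags, index=ids, name="cpg_related")


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _to_genomic(gene: GeneModel, rel_lo: int, rel_hi: int,
                anchor: int | None = None) -> tuple[int, int]:
    a = gene.tss if anchor is None else anchor
    sign = 1 if gene.strand == "+" else -1
    x, y = a + sign * rel_lo, a + sign * rel_hi
    return min(x, y), max(x, y)


def _background_tiles(
    gene: GeneModel, grid: NucleosomeGrid, control_offset: int,
    tile: int = 150,
) -> list[tuple[int, int]]:
    """150-bp background tiles covering the promoter-plus-body locus and the
    control window, laid out in transcript orientation from each anchor so
    that promoter and control windows are statistically exchangeable."""
    span_lo, span_hi = grid.span
    body_extent = gene.body_length  # body starts at the TSS
    # the promoter and control windows get byte-identical tile layouts in
    # anchor-relative coordinates, so they are exchangeable when no signal
    # is planted; the body continuation is tiled separately
    blocks_rel: list[tuple[int, int, int | None]] = [
        (span_lo, span_hi, None),
        (span_lo, span_hi, -control_offset),  # control window
    ]
    if body_extent - 1 > span_hi:
        blocks_rel.append((span_hi + 1, body_extent - 1, None))
    out: list[tuple[int, int]] = []
    for rel_lo, rel_hi, anchor_off in blocks_rel:
        anchor = None
        if anchor_off is not None:
            sign = 1 if gene.strand == "+" else -1
            anchor = gene.tss + sign * anchor_off
        pos = rel_lo
        while pos <= rel_hi:
            end = min(pos + tile - 1, rel_hi)
            out.append(_to_genomic(gene, pos, end, anchor))
            pos = end + 1
    return out


def _informative_regions(
    gene: GeneModel, grid: NucleosomeGrid,
    effects: dict[tuple[str, str], float], mark: str,
) -> list[tuple[int, int, float]]:
    """(genomic lo, hi, fold-change) spans where this mark is informative."""
    out: list[tuple[int, int, float]] = []
    for idx, (lo, hi) in zip(grid.indices, grid.intervals):
        f = effects.get((mark, f"{idx:+d}"))
        if f is not None:
            out.append((*_to_genomic(gene, lo, hi), f))
    body_f = effects.get((mark, "body"))
    first = gene.exons[0]
    for j, (s, e) in enumerate(gene.exons):
        f = effects.get((mark, "first_exon")) if j == 0 else None
        f = f if f is not None else body_f
        if f is not None:
            out.append((s, e, f))
    genomic = sorted(gene.exons)
    for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
        if s2 - 1 < e1 + 1:
            continue
        is_first = (gene.strand == "+" and (s1, e1) == first) or (
            gene.strand == "-" and (s2, e2) == first
        )
        f = effects.get((mark, "first_intron")) if is_first else None
        f = f if f is not None else body_f
        if f is not None:
            out.append((e1 + 1, s2 - 1, f))
    return out


def simulate_tags(
    design: SimulationDesign,
    genes: list[GeneModel],
    labels: pd.Series,
    control_offset: int = 50_000,
) -> list[TagTrack]:
    """Per-mark tag tracks with planted class-differential regions.

    Background tags are a homogeneous overdispersed process tiled across
    each gene locus and its control window; informative (mark, region)
    pairs add extra counts with mean (f - 1) x background for specific
    genes, so the class mean ratio at a planted cell approaches f.
    """
    rng = np.random.default_rng([design.seed, 37])
    grid = nucleosome_grid()
    effects: dict[tuple[str, str], float] = {
        (mark, region): f for mark, region, f in design.informative
    }
    group_of: dict[str, int] = {}
    for gi, group in enumerate(design.redundancy_groups):
        for mark in group:
            group_of[mark] = gi
    # one latent Bernoulli amplitude per (gene, redundancy group)
    n_groups = len(design.redundancy_groups)
    latent = rng.integers(0, 2, size=(len(genes), max(n_groups, 1)))
    is_specific = labels.loc[[g.id for g in genes]].to_numpy() == "specific"

    tiles = [_background_tiles(g, grid, control_offset) for g in genes]
    tracks: list[TagTrack] = []
    for mark in design.marks:
        los, his, means = [], [], []
        for gi, (gene, gtiles) in enumerate(zip(genes, tiles)):
            for lo, hi in gtiles:
                los.append(lo)
                his.append(hi)
                means.append(design.base_rate * (hi - lo + 1) / 150.0)
            if not is_specific[gi]:
                continue
            amp = 1.0
            if mark in group_of:
                amp = float(latent[gi, group_of[mark]])
            if amp == 0.0:
                continue
            for lo, hi, f in _informative_regions(gene, grid, effects, mark):
                los.append(lo)
                his.append(hi)
                means.append(
                    design.base_rate * (hi - lo + 1) / 150.0 * (f - 1.0) * amp
                )
        los_a = np.asarray(los, dtype=np.int64)
        his_a = np.asarray(his, dtype=np.int64)
        counts = _nb_counts(rng, np.asarray(means), design.dispersion)
        total = int(counts.sum())
        lo_rep = np.repeat(los_a, counts)
        width_rep = np.repeat(his_a - los_a + 1, counts)
        positions = lo_rep + (rng.random(total) * width_rep).astype(np.int64)
        tracks.append(
            TagTrack(mark_name=mark, tags={"chr1": np.sort(positions)})
        )
    return tracks


def make_dataset(design: SimulationDesign, outdir: str | Path) -> Path:
    """Write a self-contained fixture bundle consumed by the CLI.

    Layout: design.yaml, expression_a.tsv, expression_b.tsv, genes.bed,
    cpg.bed, truth.tsv, tags/<mark>.bed.
    """
    outdir = Path(outdir)
    (outdir / "tags").mkdir(parents=True, exist_ok=True)
    expr_a, expr_b, labels = simulate_expression(design)
    genes, cpg, cpg_flags = simulate_genome(design)
    tracks = simulate_tags(design, genes, labels)

    d = asdict(design)
    d["marks"] = list(design.marks)
    d["informative"] = [list(t) for t in design.informative]
    d["redundancy_groups"] = [list(g) for g in design.redundancy_groups]
    (outdir / "design.yaml").write_text(yaml.safe_dump(d, sort_keys=True))

    write_expression(expr_a, outdir / "expression_a.tsv")
    write_expression(expr_b, outdir / "expression_b.tsv")
    write_gene_models(genes, outdir / "genes.bed")
    lines = [
        f"chr1\t{s - 1}\t{e}\tCpG" for s, e in cpg.get("chr1", np.empty((0, 2)))
    ]
    (outdir / "cpg.bed").write_text("\n".join(lines) + ("\n" if lines else ""))
    truth = pd.DataFrame({"label": labels, "cpg_related": cpg_flags})
    truth.index.name = "gene"
    truth.to_csv(outdir / "truth.tsv", sep="\t")
    for track in tracks:
        write_tag_track(track, outdir / "tags" / f"{track.mark_name}.bed")
    return outdir


def load_design(path: str | Path) -> SimulationDesign:
    d = yaml.safe_load(Path(path).read_text())
    d["marks"] = tuple(d["marks"])
    d["informative"] = tuple(tuple(t) for t in d["informative"])
    d["redundancy_groups"] = tuple(tuple(g) for g in d["redundancy_groups"])
    return SimulationDesign(**d)
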