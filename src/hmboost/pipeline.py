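"""Stage composition helpers shared by the CLI and scripts.

A "bundle" is a self-contained directory of the formats the readers accept
(expression TSVs, gene-model BED12, CpG BED, per-mark tag BEDs), as written
by :func:`hmboost.simulate.make_dataset`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as ft
from . import specificity as sp
from .core import FeatureTable, GeneModel, TagTrack
from .evaluation import ReplicateReport, compare_to_control, replicate_experiment
from .io import read_bed_intervals, read_expression, read_gene_models, read_tag_track

__all__ = ["Bundle", "load_bundle", "call_gene_sets", "featurize", "evaluate_bundle"]


@dataclass
class Bundle:
    genes: list[GeneModel]
    cpg_islands: dict[str, np.ndarray]
    tracks: list[TagTrack]
    expression_a: pd.DataFrame
    expression_b: pd.DataFrame
    root: Path


def load_bundle(path: str | Path) -> Bundle:
    root = Path(path)
    genes = read_gene_models(root / "genes.bed")
    cpg = read_bed_intervals(root / "cpg.bed") if (root / "cpg.bed").exists() else {}
    tracks = [
        read_tag_track(p, mark_name=p.stem)
        for p in sorted((root / "tags").glob("*.bed"))
    ]
    return Bundle(
        genes=genes,
        cpg_islands=cpg,
        tracks=tracks,
        expression_a=read_expression(root / "expression_a.tsv"),
        expression_b=read_expression(root / "expression_b.tsv"),
        root=root,
    )


def call_gene_sets(
    bundle: Bundle,
    target_tissue: str = "tissue000",
    h_max: float = 5.0,
    q_max: float = 9.0,
    h_min_a: float = 6.2,
    h_min_b: float = 8.9,
) -> tuple[set[str], set[str], pd.DataFrame]:
    """Entropy-based specific and housekeeping calls from both expression
    datasets; returns (specific, housekeeping, scores_a)."""
    expr_a = sp.ingest_expression(bundle.expression_a)
    expr_b = sp.ingest_expression(bundle.expression_b)
    scores_a = sp.score_specificity(expr_a, target_tissue)
    scores_b = sp.score_specificity(expr_b, target_tissue)
    specific = sp.call_specific(scores_a, h_max=h_max, q_max=q_max)
    housekeeping = sp.call_housekeeping(scores_a, scores_b,
                                        h_min_a=h_min_a, h_min_b=h_min_b)
    return specific, housekeeping, scores_a


def featurize(bundle: Bundle, region: str = "promoter",
              control_offset: int = 50_000) -> FeatureTable:
    grid = ft.nucleosome_grid()
    if region == "promoter":
        return ft.promoter_features(bundle.genes, bundle.tracks, grid)
    if region == "body":
        return ft.body_features(bundle.genes, bundle.tracks, grid)
    if region == "control":
        return ft.control_features(bundle.genes, bundle.tracks, grid,
                                   offset=control_offset)
    raise ValueError(f"unknown region {region!r}")


def evaluate_bundle(
    table: FeatureTable,
    specific: set[str],
    housekeeping: set[str],
    control_table: FeatureTable | None = None,
    replicates: int = 100,
    folds: int = 5,
    rounds: int = 100,
    seed: int = 0,
) -> dict:
    """Balanced-resampling evaluation of specific-vs-housekeeping on a
    feature table, optionally compared against its control-region twin."""
    pos_ids = [g for g in table.genes if g in specific]
    neg_ids = [g for g in table.genes if g in housekeeping]
    pos = table.data.loc[pos_ids]
    neg = table.data.loc[neg_ids]
    report = replicate_experiment(pos, neg, replicates=replicates,
                                  folds=folds, rounds=rounds, seed=seed)
    out: dict = {"signal": report}
    if control_table is not None:
        cpos_ids = [g for g in control_table.genes if g in specific]
        cneg_ids = [g for g in control_table.genes if g in housekeeping]
        control = replicate_experiment(
            control_table.data.loc[cpos_ids], control_table.data.loc[cneg_ids],
            replicates=replicates, folds=folds, rounds=rounds, seed=seed + 1,
        )
        p, band = compare_to_control(report, control)
        report.control_p = p
        out.update({"control": control, "control_p": p, "band": band})
    return out
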