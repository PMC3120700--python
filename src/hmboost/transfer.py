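"""Cross-cell-type transfer, low-resolution-TSS prediction and the
mark-redundancy experiment.

A classifier trained on one cell type's feature table is applied to
another's, after restricting both to the marks profiled in both datasets
and (by default) normalizing tag counts to tags-per-million so that
sequencing depth does not confound the transfer.  TSS uncertainty — the
situation for miRNA genes whose promoters are computational predictions —
is emulated by jittering each TSS uniformly within a bp window before
featurization.  The redundancy experiment drops a set of marks from the
feature table and re-runs the balanced-resampling evaluation against the
full-table baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boost import predict, train
from .core import FeatureTable, GeneModel
from .evaluation import (
    ReplicateReport,
    _confusion,
    compare_to_control,
    metrics,
    replicate_experiment,
)

__all__ = [
    "TransferSpec",
    "restrict_marks",
    "normalize_depth",
    "transfer_evaluate",
    "jitter_tss",
    "redundancy_experiment",
]


def restrict_marks(table: FeatureTable, marks: list[str]) -> FeatureTable:
    """Keep only columns belonging to ``marks``; column order preserved."""
    unknown = set(marks) - set(table.marks)
    if unknown:
        raise KeyError(f"unknown mark(s): {sorted(unknown)}")
    if not marks:
        raise ValueError("cannot restrict to an empty mark set")
    keep = [c for c in table.features if c.split(":", 1)[0] in set(marks)]
    return FeatureTable(table.data[keep], table.region_kind)


def normalize_depth(
    table: FeatureTable, track_totals: dict[str, int]
) -> FeatureTable:
    """Scale each mark's columns to tags-per-million of its track depth."""
    df = table.data.copy()
    for col in df.columns:
        mark = col.split(":", 1)[0]
        total = track_totals.get(mark)
        if total:
            df[col] = df[col] * (1e6 / total)
    return FeatureTable(df, table.region_kind)


@dataclass
class TransferSpec:
    """Inputs for a cross-dataset transfer evaluation.

    Labels are +/-1 series indexed by gene id, aligned to their tables.
    Control tables, when given, provide the null baseline trained and
    evaluated on control-region features.
    """

    source_table: FeatureTable
    source_labels: pd.Series
    target_table: FeatureTable
    target_labels: pd.Series
    source_control: FeatureTable | None = None
    target_control: FeatureTable | None = None
    excluded_marks: tuple[str, ...] = ()
    source_totals: dict[str, int] | None = None
    target_totals: dict[str, int] | None = None

    @property
    def shared_marks(self) -> list[str]:
        src = set(self.source_table.marks)
        tgt = set(self.target_table.marks)
        shared = [m for m in self.source_table.marks
                  if m in tgt and m not in set(self.excluded_marks)]
        if not shared:
            raise ValueError("no shared marks between source and target")
        return shared


def _transfer_replicates(
    source: FeatureTable,
    source_labels: pd.Series,
    target: FeatureTable,
    target_labels: pd.Series,
    replicates: int,
    rounds: int,
    seed: int,
) -> ReplicateReport:
    pos_df = source.data.loc[source_labels[source_labels == 1].index]
    neg_df = source.data.loc[source_labels[source_labels == -1].index]
    if len(neg_df) < len(pos_df):
        raise ValueError("need at least as many source negatives as positives")
    rng = np.random.default_rng(seed)
    y_t = target_labels.loc[target.genes].to_numpy()
    sns, ppvs, fs = [], [], []
    n_pos = len(pos_df)
    for _ in range(replicates):
        take = rng.choice(len(neg_df), size=n_pos, replace=False)
        Xrep = pd.concat([pos_df, neg_df.iloc[np.sort(take)]], axis=0)
        yrep = np.concatenate([np.ones(n_pos), -np.ones(n_pos)])
        model = train(Xrep, yrep, rounds=rounds)
        _, pred = predict(model, target.data)
        sn, ppv, f = metrics(_confusion(y_t, pred))
        sns.append(sn)
        ppvs.append(ppv)
        fs.append(f)
    return ReplicateReport(
        sensitivity=np.asarray(sns), ppv=np.asarray(ppvs), fscore=np.asarray(fs)
    )


def transfer_evaluate(
    spec: TransferSpec,
    replicates: int = 100,
    rounds: int = 100,
    seed: int = 0,
) -> dict:
    """Train on the source cell type, evaluate on the target.

    Returns the signal report plus, when control tables are supplied, the
    control-trained baseline report and the rank-sum p-value between the
    per-replicate F-scores.
    """
    marks = spec.shared_marks
    src = restrict_marks(spec.source_table, marks)
    tgt = restrict_marks(spec.target_table, marks)
    if spec.source_totals:
        src = normalize_depth(src, spec.source_totals)
    if spec.target_totals:
        tgt = normalize_depth(tgt, spec.target_totals)
    signal = _transfer_replicates(
        src, spec.source_labels, tgt, spec.target_labels,
        replicates, rounds, seed,
    )
    out = {"shared_marks": marks, "signal": signal}
    if spec.source_control is not None and spec.target_control is not None:
        src_c = restrict_marks(spec.source_control, marks)
        tgt_c = restrict_marks(spec.target_control, marks)
        if spec.source_totals:
            src_c = normalize_depth(src_c, spec.source_totals)
        if spec.target_totals:
            tgt_c = normalize_depth(tgt_c, spec.target_totals)
        control = _transfer_replicates(
            src_c, spec.source_labels, tgt_c, spec.target_labels,
            replicates, rounds, seed + 1,
        )
        p, band = compare_to_control(signal, control)
        out.update({"control": control, "control_p": p, "band": band})
    return out


def jitter_tss(
    genes: list[GeneModel], max_offset: int = 500, seed: int = 0
) -> list[GeneModel]:
    """Perturb each TSS by a uniform integer offset in [-max_offset,
    +max_offset] along the transcript direction.

    The first exon's 5' boundary moves with the TSS (clamped so the exon
    keeps at least 1 bp), emulating promoter annotations of limited
    resolution while keeping gene models self-consistent.
    """
    if max_offset < 0:
        raise ValueError("max_offset must be >= 0")
    if max_offset == 0:
        return list(genes)
    rng = np.random.default_rng(seed)
    out: list[GeneModel] = []
    for g in genes:
        d = int(rng.integers(-max_offset, max_offset + 1))
        s, e = g.exons[0]
        if g.strand == "+":
            new_start = min(max(1, g.tss + d), e)
            exons = ((new_start, e),) + g.exons[1:]
            tss = new_start
        else:
            new_end = max(g.tss - d, s)
            exons = ((s, new_end),) + g.exons[1:]
            tss = new_end
        out.append(GeneModel(id=g.id, chrom=g.chrom, strand=g.strand,
                             tss=tss, exons=exons, cpg_related=g.cpg_related))
    return out


def redundancy_experiment(
    table: FeatureTable,
    labels: pd.Series,
    drop: list[str],
    replicates: int = 100,
    folds: int = 5,
    rounds: int = 100,
    seed: int = 0,
) -> dict:
    """Balanced-resampling evaluation with ``drop`` marks removed, paired
    with the full-table baseline under the same seed."""
    unknown = set(drop) - set(table.marks)
    if unknown:
        raise KeyError(f"unknown mark(s): {sorted(unknown)}")
    remaining = [m for m in table.marks if m not in set(drop)]
    if not remaining:
        raise ValueError("cannot drop every mark")

    def run(t: FeatureTable) -> ReplicateReport:
        pos = t.data.loc[labels[labels == 1].index]
        neg = t.data.loc[labels[labels == -1].index]
        return replicate_experiment(pos, neg, replicates=replicates,
                                    folds=folds, rounds=rounds, seed=seed)

    dropped_table = restrict_marks(table, remaining) if drop else table
    return {
        "dropped_marks": list(drop),
        "dropped": run(dropped_table),
        "full": run(table),
    }
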