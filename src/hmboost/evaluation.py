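"""Performance evaluation: metrics, stratified k-fold CV, balanced
resampling replicates, control-region comparison and profile correlations.

Sensitivity = TP/(TP+FN), PPV = TP/(TP+FP), F = 2*Sn*PPV/(Sn+PPV) (0 when
Sn+PPV = 0; NaN when a denominator is empty).  The balanced-resampling
experiment mirrors the training protocol for an unbalanced design: per
replicate, sample as many negatives (without replacement) as there are
positives, run stratified 5-fold CV for the metrics, then train on the full
replicate set and record which feature the first boosting round selected.
Signal-vs-control and gene-set comparisons use the two-sided Wilcoxon
rank-sum test.

For comparison against published two-decimal tables, metric triples are also
rendered *truncated* (not rounded) to two decimals.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .boost import predict, top_features, train
from .core import BoostModel, FeatureTable

__all__ = [
    "ConfusionCounts",
    "ReplicateReport",
    "metrics",
    "truncate2",
    "kfold",
    "cross_validate",
    "replicate_experiment",
    "compare_to_control",
    "significance_band",
    "significance_stars",
    "selection_share",
    "profile_correlation",
    "compare_gene_sets",
    "evaluate_external_geneset",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FP + other.FP,
            self.TN + other.TN, self.FN + other.FN,
        )


def metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, PPV, F-score); NaN marks an undefined denominator."""
    sn = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else float("nan")
    ppv = c.TP / (c.TP + c.FP) if (c.TP + c.FP) > 0 else float("nan")
    if math.isnan(sn) or math.isnan(ppv):
        f = float("nan")
    elif sn + ppv == 0:
        f = 0.0
    else:
        f = 2 * sn * ppv / (sn + ppv)
    return sn, ppv, f


def truncate2(x: float) -> float:
    """Truncate (not round) to two decimals, the published-table rendering."""
    if math.isnan(x):
        return x
    return math.trunc(x * 100) / 100


def kfold(labels: np.ndarray, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Class-stratified partition of sample indices into k folds."""
    labels = np.asarray(labels)
    if len(labels) < k:
        raise ValueError(f"need at least {k} samples for {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == -1) & (y_pred == 1)))
    tn = int(np.sum((y_true == -1) & (y_pred == -1)))
    fn = int(np.sum((y_true == 1) & (y_pred == -1)))
    return ConfusionCounts(tp, fp, tn, fn)


def cross_validate(
    X, y, k: int = 5, seed: int = 0, rounds: int = 100
) -> dict:
    """Stratified k-fold CV; reported metrics are the mean over folds."""
    if isinstance(X, FeatureTable):
        X = X.data
    Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    y = np.asarray(y, dtype=float)
    folds = kfold(y, k=k, seed=seed)
    pooled = ConfusionCounts(0, 0, 0, 0)
    per_fold = []
    for test_idx in folds:
        mask = np.zeros(len(y), dtype=bool)
        mask[test_idx] = True
        Xtr = pd.DataFrame(Xm[~mask], columns=names) if names else Xm[~mask]
        Xte = pd.DataFrame(Xm[mask], columns=names) if names else Xm[mask]
        model = train(Xtr, y[~mask], rounds=rounds)
        _, pred = predict(model, Xte)
        c = _confusion(y[mask], pred)
        pooled = pooled + c
        per_fold.append(metrics(c))
    arr = np.asarray(per_fold, dtype=float)
    mean = tuple(np.nanmean(arr, axis=0))
    return {
        "pooled": pooled,
        "per_fold": per_fold,
        "sensitivity": mean[0],
        "ppv": mean[1],
        "fscore": mean[2],
    }


@dataclass
class ReplicateReport:
    """Aggregate of a balanced-resampling experiment."""

    sensitivity: np.ndarray            # per replicate
    ppv: np.ndarray
    fscore: np.ndarray
    top_feature_counts: Counter = field(default_factory=Counter)
    models: list[BoostModel] = field(default_factory=list)
    control_p: float | None = None

    @property
    def n_replicates(self) -> int:
        return len(self.fscore)

    def summary(self) -> dict:
        def ms(a: np.ndarray) -> dict:
            return {"mean": float(np.nanmean(a)), "sd": float(np.nanstd(a, ddof=1))
                    if len(a) > 1 else 0.0}

        return {
            "replicates": self.n_replicates,
            "sensitivity": ms(self.sensitivity),
            "ppv": ms(self.ppv),
            "fscore": ms(self.fscore),
            "top_feature_counts": dict(self.top_feature_counts),
            "control_p": self.control_p,
        }


def replicate_experiment(
    pos: FeatureTable | pd.DataFrame,
    neg: FeatureTable | pd.DataFrame,
    replicates: int = 100,
    folds: int = 5,
    rounds: int = 100,
    seed: int = 0,
    keep_models: bool = False,
) -> ReplicateReport:
    """Balanced resampling: per replicate draw |pos| negatives without
    replacement, cross-validate, and record the top selected feature of the
    full-replicate model."""
    pos_df = pos.data if isinstance(pos, FeatureTable) else pos
    neg_df = neg.data if isinstance(neg, FeatureTable) else neg
    if list(pos_df.columns) != list(neg_df.columns):
        raise ValueError("positive and negative tables have different features")
    if len(neg_df) < len(pos_df):
        raise ValueError("need at least as many negatives as positives")
    rng = np.random.default_rng(seed)
    sns, ppvs, fs = [], [], []
    counts: Counter = Counter()
    models: list[BoostModel] = []
    n_pos = len(pos_df)
    for _ in range(replicates):
        take = rng.choice(len(neg_df), size=n_pos, replace=False)
        Xrep = pd.concat([pos_df, neg_df.iloc[np.sort(take)]], axis=0)
        yrep = np.concatenate([np.ones(n_pos), -np.ones(n_pos)])
        cv_seed = int(rng.integers(0, 2**31 - 1))
        res = cross_validate(Xrep, yrep, k=folds, seed=cv_seed, rounds=rounds)
        sns.append(res["sensitivity"])
        ppvs.append(res["ppv"])
        fs.append(res["fscore"])
        full = train(Xrep, yrep, rounds=rounds)
        if full.stumps:
            counts[top_features(full, 1)[0]] += 1
        if keep_models:
            models.append(full)
    return ReplicateReport(
        sensitivity=np.asarray(sns),
        ppv=np.asarray(ppvs),
        fscore=np.asarray(fs),
        top_feature_counts=counts,
        models=models,
    )


def compare_to_control(
    report_signal: ReplicateReport, report_control: ReplicateReport
) -> tuple[float, str]:
    """Two-sided Wilcoxon rank-sum on per-replicate F-scores, with the
    published significance band symbol ('' <1e-5, '*' <1e-2, '+' >=1e-2)."""
    if report_signal.n_replicates != report_control.n_replicates:
        raise ValueError("replicate counts differ")
    if report_signal.n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    a, b = report_signal.fscore, report_control.fscore
    if np.array_equal(a, b):
        p = 1.0
    else:
        p = float(stats.ranksums(a, b).pvalue)
    return p, significance_band(p)


def significance_band(p: float) -> str:
    """Table-style symbol: '' for p<1e-5, '*' for 1e-5<=p<1e-2, '+' else."""
    if p < 1e-5:
        return ""
    if p < 1e-2:
        return "*"
    return "+"


def significance_stars(p: float) -> str:
    """Figure-style stars: '**' for p<1e-4, '*' for p<0.05, '' otherwise."""
    if p < 1e-4:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def selection_share(k: int, n: int) -> int:
    """Share k/n rendered as a whole percentage (e.g. 13 of 15 -> 87)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return round(100 * k / n)


def profile_correlation(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> tuple[pd.Series, float]:
    """Per-gene Pearson r between two marks' promoter profiles, and the
    median r.  Genes with a constant profile in either mark are excluded."""
    if table_a.shape != table_b.shape:
        raise ValueError("profile tables must have identical shape")
    a = table_a.to_numpy(dtype=float)
    b = table_b.to_numpy(dtype=float)
    ok = (a.std(axis=1) > 0) & (b.std(axis=1) > 0)
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (az * bz).sum(axis=1) / np.sqrt(
            (az**2).sum(axis=1) * (bz**2).sum(axis=1)
        )
    r = np.where(ok, r, np.nan)
    series = pd.Series(r, index=table_a.index, name="pearson_r")
    valid = series.dropna()
    median = float(valid.median()) if len(valid) else float("nan")
    return series, median


def compare_gene_sets(
    densities_a: np.ndarray, densities_b: np.ndarray
) -> tuple[float, str]:
    """Two-sided rank-sum between two sets of regional signal densities,
    with figure-style significance stars."""
    a = np.asarray(densities_a, dtype=float)
    b = np.asarray(densities_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both gene sets must be non-empty")
    p = float(stats.ranksums(a, b).pvalue)
    return p, significance_stars(p)


def evaluate_external_geneset(
    predicted: set[str], truth_pos: set[str], universe: set[str]
) -> dict:
    """Set-overlap confusion counts and metrics for an externally defined
    gene set judged against a truth set, with the two-decimal truncated
    rendering used for published comparisons."""
    if not predicted <= universe or not truth_pos <= universe:
        raise ValueError("predicted and truth sets must lie in the universe")
    tp = len(predicted & truth_pos)
    fp = len(predicted - truth_pos)
    fn = len(truth_pos - predicted)
    tn = len(universe) - tp - fp - fn
    c = ConfusionCounts(tp, fp, tn, fn)
    sn, ppv, f = metrics(c)
    return {
        "confusion": c,
        "sensitivity": sn,
        "ppv": ppv,
        "fscore": f,
        "truncated": (truncate2(sn), truncate2(ppv), truncate2(f)),
    }
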