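"""Boosting with decision stumps, with per-round feature bookkeeping.

The classifier is discrete AdaBoost over one-split decision trees: each
round fits the stump (feature, threshold, polarity) minimizing the weighted
0/1 error over all features, both polarities and all thresholds placed at
midpoints between consecutive distinct sorted values (plus -inf/+inf
sentinels); the stump gets vote alpha = 0.5*ln((1-eps)/eps) and sample
weights are reweighted by exp(-alpha * y * h(x)) and renormalized.

Training is deterministic given its input — all stochasticity in the
pipeline lives in resampling.  Feature selection is read off the trained
model: the "top predictive feature" is the feature of the first-round stump,
the single stump with the greatest standalone weighted-error reduction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import BoostModel, FeatureTable, Stump

__all__ = ["best_stump", "train", "predict", "top_features"]

_EPS_FLOOR = 1e-12  # clamp for alpha when a stump is perfect


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, FeatureTable):
        X = X.data
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    return arr, [f"f{i}" for i in range(arr.shape[1])]


def _presort(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(X, axis=0, kind="stable")
    xs = np.take_along_axis(X, order, axis=0)
    return order, xs


def _search(
    xs: np.ndarray, order: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[int, int, int, float]:
    """Best (feature, split position, polarity, weighted error) given sorted
    feature values ``xs`` and sort ``order``.

    Split position i means threshold between sorted positions i-1 and i
    (i = 0 -> -inf, i = n -> +inf).  With total weight W = sum(w) and signed
    prefix sums c_i = sum_{j<i} w_j*y_j in sorted order, the error of the
    polarity-(+1) stump at split i is c_i + (W - S)/2 where S = c_n, and the
    polarity-(-1) error is W minus that.
    """
    n, F = xs.shape
    wy = (w * y)[order]                       # (n, F)
    cum = np.vstack([np.zeros(F), np.cumsum(wy, axis=0)])  # (n+1, F)
    W = float(w.sum())
    S = cum[-1, 0]
    err_plus = cum + (W - S) / 2.0
    err_minus = W - err_plus
    # forbid splits inside runs of equal values
    invalid = np.zeros((n + 1, F), dtype=bool)
    invalid[1:n] = xs[1:] == xs[:-1]
    err_plus = np.where(invalid, np.inf, err_plus)
    err_minus = np.where(invalid, np.inf, err_minus)
    # tie-break: lowest feature index, then smallest threshold (ascending
    # split position), then polarity +1 — achieved by C-order argmin over
    # (feature, position, polarity)
    stacked = np.stack([err_plus.T, err_minus.T], axis=-1)  # (F, n+1, 2)
    flat = int(np.argmin(stacked))
    f, rest = divmod(flat, (n + 1) * 2)
    i, p = divmod(rest, 2)
    polarity = 1 if p == 0 else -1
    return f, i, polarity, float(stacked.reshape(-1)[flat])


def _threshold_at(xs_col: np.ndarray, i: int) -> float:
    n = xs_col.shape[0]
    if i == 0:
        return float("-inf")
    if i == n:
        return float("inf")
    return float((xs_col[i - 1] + xs_col[i]) / 2.0)


def best_stump(X, y, w=None) -> Stump:
    """Exhaustive weighted-error-minimizing stump (single weak learner)."""
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n = Xm.shape[0]
    if w is None:
        w = np.full(n, 1.0 / n)
    w = np.asarray(w, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    if Xm.shape[1] < 1:
        raise ValueError("at least one feature required")
    if len(np.unique(y)) < 2:
        # degenerate: a -inf-threshold stump predicting the single class
        pol = int(y[0])
        return Stump(names[0], float("-inf"), pol, 0.0, 0.0)
    order, xs = _presort(Xm)
    f, i, polarity, err = _search(xs, order, y, w)
    eps = err / w.sum()
    eps_c = min(max(eps, _EPS_FLOOR), 1 - _EPS_FLOOR)
    alpha = 0.5 * np.log((1 - eps_c) / eps_c)
    return Stump(names[f], _threshold_at(xs[:, f], i), polarity, eps, float(alpha))


def train(X, y, rounds: int = 100) -> BoostModel:
    """Discrete AdaBoost over stumps.

    Stops early when a round's best stump is perfect (eps = 0, nothing left
    to reweight) or no better than chance (eps >= 0.5).
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, (-1.0, 1.0))) or len(classes) < 2:
        raise ValueError("labels must contain both classes, coded as +/-1")
    n = Xm.shape[0]
    order, xs = _presort(Xm)
    w = np.full(n, 1.0 / n)
    stumps: list[Stump] = []
    for _ in range(rounds):
        f, i, polarity, err = _search(xs, order, y, w)
        eps = err / w.sum()
        if eps >= 0.5:
            break
        eps_c = max(eps, _EPS_FLOOR)
        alpha = 0.5 * np.log((1 - eps_c) / eps_c)
        thr = _threshold_at(xs[:, f], i)
        stump = Stump(names[f], thr, polarity, eps, float(alpha))
        stumps.append(stump)
        if eps <= _EPS_FLOOR:
            break
        h = stump.decide(Xm[:, f])
        w = w * np.exp(-stump.weight * y * h)
        w = w / w.sum()
    return BoostModel(stumps=stumps, feature_names=names)


def predict(model: BoostModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Additive scores sum(alpha*h) and hard labels (score 0 -> -1)."""
    if isinstance(X, FeatureTable):
        X = X.data
    if isinstance(X, pd.DataFrame):
        missing = [f for f in {s.feature for s in model.stumps}
                   if f not in X.columns]
        if missing:
            raise KeyError(f"feature(s) missing from input: {sorted(missing)}")
        col = {c: X[c].to_numpy(dtype=float) for c in X.columns}
        n = len(X)
    else:
        Xm = np.asarray(X, dtype=float)
        names = [f"f{i}" for i in range(Xm.shape[1])]
        if not set(s.feature for s in model.stumps) <= set(names):
            raise KeyError("feature matrix narrower than model's features")
        col = {nm: Xm[:, i] for i, nm in enumerate(names)}
        n = Xm.shape[0]
    scores = np.zeros(n)
    for s in model.stumps:
        scores += s.weight * s.decide(col[s.feature])
    labels = np.where(scores > 0, 1, -1)
    return scores, labels


def top_features(model: BoostModel, k: int | None = None,
                 by: str = "first_round") -> list[str]:
    """Ranked selected features.

    ``by="first_round"`` (default): rank 1 is the first-round stump's feature
    (the top predictive feature), later ranks by first round of appearance.
    ``by="total_alpha"``: rank by summed |alpha| across all rounds.
    """
    if by == "first_round":
        seen: dict[str, None] = {}
        for s in model.stumps:
            seen.setdefault(s.feature)
        ranked = list(seen)
    elif by == "total_alpha":
        totals: dict[str, float] = {}
        for s in model.stumps:
            totals[s.feature] = totals.get(s.feature, 0.0) + abs(s.weight)
        ranked = sorted(totals, key=lambda f: (-totals[f], model.feature_names.index(f)))
    else:
        raise ValueError(f"unknown ranking {by!r}")
    return ranked if k is None else ranked[:k]
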