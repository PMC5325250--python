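"""Predictive models for parenchymal hemorrhage (PH).

Implements the published fixed-coefficient logistic score and the
published two-threshold classification tree, together with the fitting
procedures that produce such models from a cohort table: backward
(stepdown) logistic regression by IRLS with Wald elimination, binary
recursive partitioning with Gini splits, single-classifier threshold
optimization, and the accuracy / ROC metrics.

Published constants::

    logit score = 1.75 - 9.526 * cbv_p10 + 2.7924 * k2_p90   (PH iff score >= -1.45)
    tree: no PH iff cbv_p10 >= 0.47 and k2_p90 < 0.28
          PH    iff cbv_p10 <  0.47 and k2_p90 >= 0.28
          (mixed quadrants resolved by a configurable policy)

The printed score formula reads "1.75 to 9.526 ..."; the sign is taken
as minus, which is required both for low CBV to raise risk and for the
worked example (cbv_p10=0.40, k2_p90=0.32 -> score -1.1668 -> PH).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, spearmanr

__all__ = [
    "LogisticModel",
    "TreeModel",
    "ConfusionCounts",
    "AccuracyReport",
    "published_logistic",
    "published_tree",
    "logistic_score",
    "tree_predict",
    "fit_logistic_backward",
    "fit_tree",
    "evaluate",
    "evaluate_counts",
    "optimal_threshold",
    "feature_correlations",
    "TREE_POLICIES",
]

#: Valid mixed-quadrant resolution policies for the two-threshold tree.
TREE_POLICIES = ("logistic_fallback", "root_cbv", "majority_leaf")


@dataclass
class LogisticModel:
    """Linear logistic score with a decision threshold on the linear scale.

    ``predict PH iff intercept + sum(coef * feature) >= threshold`` —
    a score exactly at the threshold counts as PH.
    """

    intercept: float
    coefficients: dict[str, float]
    threshold: float
    fitted: bool = False
    converged: bool = True
    separation_flag: bool = False
    standard_errors: dict[str, float] | None = None

    def to_dict(self) -> dict:
        return {
            "kind": "logistic",
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "threshold": self.threshold,
            "fitted": self.fitted,
            "converged": self.converged,
            "separation_flag": self.separation_flag,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticModel":
        return cls(
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            threshold=float(d["threshold"]),
            fitted=bool(d.get("fitted", False)),
        )


@dataclass
class TreeModel:
    """Classification tree.

    Two representations share this type:

    * ``kind="quadrant"`` — the published two-threshold rule on
      (cbv_p10, k2_p90) with a mixed-quadrant ``policy`` tag;
    * ``kind="fitted"`` — a recursive binary tree grown by
      :func:`fit_tree`; ``root`` is a nested dict of split nodes
      ``{"feature", "threshold", "left", "right"}`` and leaves
      ``{"label"}`` (left branch is ``feature < threshold``).
    """

    kind: str = "quadrant"
    cbv_threshold: float = 0.47
    k2_threshold: float = 0.28
    policy: str = "logistic_fallback"
    root: dict | None = None
    fallback: "LogisticModel | None" = None

    def __post_init__(self) -> None:
        if self.kind not in ("quadrant", "fitted"):
            raise ValueError(f"unknown tree kind {self.kind!r}")
        if self.kind == "quadrant" and self.policy not in TREE_POLICIES:
            raise ValueError(
                f"unknown mixed-quadrant policy {self.policy!r}; choose from {TREE_POLICIES}"
            )

    def thresholds(self) -> dict[str, list[float]]:
        """All split thresholds per feature, in encounter order."""
        if self.kind == "quadrant":
            return {"cbv_p10": [self.cbv_threshold], "k2_p90": [self.k2_threshold]}
        out: dict[str, list[float]] = {}

        def walk(node: dict) -> None:
            if "label" in node:
                return
            out.setdefault(node["feature"], []).append(node["threshold"])
            walk(node["left"])
            walk(node["right"])

        walk(self.root or {"label": 0})
        return out

    def to_dict(self) -> dict:
        d = {"kind": "tree", "tree_kind": self.kind, "policy": self.policy}
        if self.kind == "quadrant":
            d.update(cbv_threshold=self.cbv_threshold, k2_threshold=self.k2_threshold)
        else:
            d["root"] = self.root
        return d


def published_logistic() -> LogisticModel:
    """The published fixed-coefficient logistic score."""
    return LogisticModel(
        intercept=1.75,
        coefficients={"cbv_p10": -9.526, "k2_p90": 2.7924},
        threshold=-1.45,
        fitted=False,
    )


def published_tree(policy: str = "logistic_fallback") -> TreeModel:
    """The published two-threshold tree (CBV10 at 0.47, K2_90 at 0.28)."""
    return TreeModel(kind="quadrant", cbv_threshold=0.47, k2_threshold=0.28, policy=policy)


def _get_feature(record, name: str) -> float:
    if isinstance(record, Mapping):
        if name not in record:
            raise KeyError(f"missing feature {name!r} in record")
        v = record[name]
    else:
        v = getattr(record, name, None)
    if v is None or not np.isfinite(v):
        raise KeyError(f"missing or non-finite feature {name!r} in record")
    return float(v)


def logistic_score(record, model: LogisticModel) -> tuple[float, int]:
    """Evaluate the logistic linear score and its decision.

    Returns ``(score, label)`` where label 1 means predicted PH;
    a score exactly at the threshold predicts PH.
    """
    score = model.intercept
    for name, coef in model.coefficients.items():
        score += coef * _get_feature(record, name)
    return score, int(score >= model.threshold)


def _predict_fitted(node: dict, record) -> int:
    while "label" not in node:
        v = _get_feature(record, node["feature"])
        node = node["left"] if v < node["threshold"] else node["right"]
    return int(node["label"])


def tree_predict(record, model: TreeModel) -> int:
    """Predicted label (1 = PH) from a classification tree.

    For the published quadrant rule: no-PH when CBV10 is high and K2_90
    low, PH when CBV10 is low and K2_90 high; the two mixed quadrants are
    resolved by the model's policy (default: fall back to the published
    logistic score).
    """
    if model.kind == "fitted":
        if model.root is None:
            raise ValueError("fitted tree has no root")
        return _predict_fitted(model.root, record)

    cbv = _get_feature(record, "cbv_p10")
    k2 = _get_feature(record, "k2_p90")
    low_cbv = cbv < model.cbv_threshold
    high_k2 = k2 >= model.k2_threshold
    if not low_cbv and not high_k2:
        return 0
    if low_cbv and high_k2:
        return 1
    # mixed quadrant
    if model.policy == "logistic_fallback":
        fallback = model.fallback or published_logistic()
        return logistic_score(record, fallback)[1]
    if model.policy == "root_cbv":
        return int(low_cbv)
    if model.policy == "majority_leaf":
        return 0  # no-PH is the majority class in the published cohort
    raise ValueError(f"unknown mixed-quadrant policy {model.policy!r}")


# ---------------------------------------------------------------------------
# metrics


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer; got {v}")
            setattr(self, name, int(v))

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


@dataclass
class AccuracyReport:
    """Sensitivity/specificity in percent; overall = (sens + spec) / 2.

    Fields are None when undefined (single-class labels, or no scores
    supplied for the AUC).
    """

    sensitivity: float | None
    specificity: float | None
    overall: float | None
    auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "overall_accuracy_pct": self.overall,
            "auc": self.auc,
        }


def auc_mann_whitney(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC area via the rank (Mann-Whitney) formulation, half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate_counts(counts: ConfusionCounts, auc: float | None = None) -> AccuracyReport:
    """Accuracy report from confusion counts; overall is exactly (sens+spec)/2."""
    sens = 100.0 * counts.tp / counts.positives if counts.positives else None
    spec = 100.0 * counts.tn / counts.negatives if counts.negatives else None
    overall = (sens + spec) / 2.0 if sens is not None and spec is not None else None
    return AccuracyReport(sens, spec, overall, auc)


def evaluate(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    scores: Sequence[float] | None = None,
) -> tuple[ConfusionCounts, AccuracyReport]:
    """Confusion counts and accuracy report for binary predictions.

    If ``scores`` are supplied (higher = more PH-like) the AUC is
    computed by the Mann-Whitney rank formulation with half credit for
    ties. With single-class labels the undefined rate is reported as
    None rather than raising.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("predictions and labels must have equal length")
    if not np.isin(y_true, (0, 1)).all() or not np.isin(y_pred, (0, 1)).all():
        raise ValueError("labels and predictions must be binary (0/1)")

    counts = ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
    )
    auc = None
    if scores is not None and counts.positives and counts.negatives:
        auc = auc_mann_whitney(scores, y_true)
    return counts, evaluate_counts(counts, auc)


# ---------------------------------------------------------------------------
# fitting


def _irls(
    X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, bool, bool]:
    """Logistic maximum likelihood by iteratively reweighted least squares.

    Returns (beta, standard_errors, converged, separation_flag). On
    detected separation (diverging coefficients) the last stable iterate
    is returned with the flag set.
    """
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    separation = False
    last_stable = beta.copy()
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        xtw = X.T * w
        try:
            beta_new = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError:
            separation = True
            break
        delta = np.abs(beta_new - beta).max()
        if np.abs(beta_new).max() > 1e3:
            separation = True
            beta = beta_new
            break
        last_stable = beta_new.copy()
        beta = beta_new
        if delta < tol:
            converged = True
            break
    if separation:
        beta = last_stable
    elif not converged and np.abs(beta).max() > 10.0:
        # coefficients drifting to huge odds ratios without converging:
        # quasi-separated data (weight clipping slows the divergence)
        separation = True

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    try:
        cov = np.linalg.inv((X.T * w) @ X)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return beta, se, converged, separation


def fit_logistic_backward(
    table: pd.DataFrame,
    candidates: Sequence[str],
    alpha: float = 0.05,
    label_column: str = "ph_label",
    threshold: float = 0.0,
) -> LogisticModel:
    """Backward-stepdown logistic regression.

    Fits the full model by IRLS, then repeatedly drops the candidate with
    the largest Wald p-value above ``alpha`` and refits, until every
    remaining candidate has p <= alpha. Constant (zero-variance)
    candidates are dropped up front with a singularity warning. On
    perfect separation the model is returned flagged, with coefficients
    at the last stable iterate.

    The returned decision threshold is on the linear-score scale
    (default 0.0, i.e. probability 0.5).
    """
    if len(table) < 10:
        raise ValueError("need at least 10 rows to fit")
    y = table[label_column].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both labels must be present")

    kept = []
    for c in candidates:
        col = table[c].to_numpy(dtype=float)
        if np.std(col) == 0:
            warnings.warn(f"candidate {c!r} is constant; dropped (singular design)")
        else:
            kept.append(c)

    separation_any = False
    converged = True
    while True:
        X = np.column_stack([np.ones(len(table))] + [table[c].to_numpy(dtype=float) for c in kept])
        beta, se, converged, separation = _irls(X, y)
        if separation:
            separation_any = True
            warnings.warn("perfect separation detected; coefficients at last stable iterate")
            break
        if not kept:
            break
        z = np.abs(beta[1:]) / se[1:]
        pvals = 2.0 * norm.sf(z)
        worst = int(np.argmax(pvals))
        if pvals[worst] > alpha:
            kept.pop(worst)
        else:
            break

    return LogisticModel(
        intercept=float(beta[0]),
        coefficients={c: float(b) for c, b in zip(kept, beta[1:])},
        threshold=threshold,
        fitted=True,
        converged=converged,
        separation_flag=separation_any,
        standard_errors={c: float(s) for c, s in zip(kept, se[1:])},
    )


def _gini(y: np.ndarray) -> float:
    if y.size == 0:
        return 0.0
    p = y.mean()
    return 2.0 * p * (1.0 - p)


def _majority(y: np.ndarray) -> int:
    ones = int(y.sum())
    zeros = y.size - ones
    return 1 if ones > zeros else 0  # ties -> negative label


def _grow_tree(
    X: np.ndarray, y: np.ndarray, features: Sequence[str], depth: int, max_depth: int, min_leaf: int
) -> dict:
    if depth >= max_depth or y.size < 2 * min_leaf or len(np.unique(y)) < 2:
        return {"label": _majority(y)}

    parent_gini = _gini(y)
    best = None  # (decrease, feature_index, threshold)
    for fi in range(X.shape[1]):
        vals = np.unique(X[:, fi])
        if vals.size < 2:
            continue
        for thr in (vals[:-1] + vals[1:]) / 2.0:
            left = X[:, fi] < thr
            n_l = int(left.sum())
            n_r = y.size - n_l
            if n_l < min_leaf or n_r < min_leaf:
                continue
            decrease = parent_gini - (n_l * _gini(y[left]) + n_r * _gini(y[~left])) / y.size
            # strict > keeps the first (lowest feature index, lowest
            # threshold) candidate on ties
            if best is None or decrease > best[0]:
                best = (decrease, fi, float(thr))
    if best is None or best[0] <= 0:
        return {"label": _majority(y)}

    _, fi, thr = best
    left = X[:, fi] < thr
    return {
        "feature": features[fi],
        "threshold": thr,
        "left": _grow_tree(X[left], y[left], features, depth + 1, max_depth, min_leaf),
        "right": _grow_tree(X[~left], y[~left], features, depth + 1, max_depth, min_leaf),
    }


def fit_tree(
    table: pd.DataFrame,
    candidates: Sequence[str],
    max_depth: int = 2,
    min_leaf: int = 5,
    label_column: str = "ph_label",
) -> TreeModel:
    """Binary recursive partitioning with exhaustive Gini splits.

    Candidate thresholds are the midpoints between consecutive sorted
    unique feature values; the split maximizing the Gini impurity
    decrease is chosen, ties broken by lower feature index then lower
    threshold. Recursion stops at ``max_depth``, at fewer than
    ``2 * min_leaf`` samples, or at a pure node; a node with no
    admissible split becomes a majority leaf (ties -> negative label).
    """
    if len(table) < 10:
        raise ValueError("need at least 10 rows to fit")
    X = np.column_stack([table[c].to_numpy(dtype=float) for c in candidates])
    y = table[label_column].to_numpy(dtype=int)
    root = _grow_tree(X, y, list(candidates), 0, max_depth, min_leaf)
    return TreeModel(kind="fitted", root=root)


def optimal_threshold(
    values: Sequence[float], labels: Sequence[int], direction: str
) -> tuple[float | None, AccuracyReport | None]:
    """Single-classifier threshold maximizing (sensitivity+specificity)/2.

    Scans all midpoints between consecutive sorted unique values.
    ``direction`` is ``"low-predicts-PH"`` (predict PH iff value <=
    threshold) or ``"high-predicts-PH"`` (predict PH iff value >=
    threshold). Ties go to the lower threshold. A constant feature has
    no threshold: returns (None, None) with a warning.
    """
    if direction not in ("low-predicts-PH", "high-predicts-PH"):
        raise ValueError(f"unknown direction {direction!r}")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(values)
    if uniq.size < 2:
        warnings.warn("constant feature: no threshold exists")
        return None, None

    best_thr = None
    best_report = None
    for thr in (uniq[:-1] + uniq[1:]) / 2.0:
        pred = (values <= thr) if direction == "low-predicts-PH" else (values >= thr)
        _, report = evaluate(labels, pred.astype(int))
        if report.overall is None:
            continue
        if best_report is None or report.overall > best_report.overall:
            best_thr, best_report = float(thr), report
    return best_thr, best_report


def feature_correlations(
    table: pd.DataFrame,
    columns: Sequence[str] = ("cbv_p10", "adc_p10", "k2_p90"),
) -> dict[tuple[str, str], float | None]:
    """Pairwise Spearman rank correlations (average ranks for ties).

    Constant columns yield None for their pairs.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    out: dict[tuple[str, str], float | None] = {}
    for i, a in enumerate(columns):
        for b in columns[i + 1:]:
            xa = table[a].to_numpy(dtype=float)
            xb = table[b].to_numpy(dtype=float)
            if np.std(xa) == 0 or np.std(xb) == 0:
                out[(a, b)] = None
                continue
            rs = spearmanr(xa, xb).statistic
            out[(a, b)] = float(rs)
    return out
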