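"""Discriminating multichannel block from selective hERG block.

Implements the classification layer: logistic-regression scores on one or
two placebo-corrected biomarkers, ROC AUC by the Mann-Whitney pair
formulation with stratified bootstrap confidence intervals, DeLong's test
for comparing paired AUCs, a fixed two-threshold decision rule on
(ddJ-Tpeakc, ddQTc), and a small depth-2 gain-ratio threshold learner with
stratified cross-validation.  The positive class throughout is
"multichannel" (hERG + late sodium-current block).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "POSITIVE_CLASS",
    "LogisticModel",
    "RocResult",
    "TreeRule",
    "logistic_fit",
    "roc_auc",
    "auc_bootstrap_ci",
    "delong_test",
    "tree_classify",
    "learn_tree",
    "evaluate_classifier",
]

POSITIVE_CLASS = "multichannel"
NEGATIVE_CLASS = "hERG"
INCONCLUSIVE = "inconclusive"


def _binary_labels(labels) -> np.ndarray:
    y = np.asarray([1 if l == POSITIVE_CLASS else 0 for l in labels])
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return y


# ---------------------------------------------------------------------------
# Logistic scores
# ---------------------------------------------------------------------------


@dataclass
class LogisticModel:
    feature_names: tuple[str, ...]
    coef: np.ndarray  # [intercept, b1, (b2)]
    converged: bool
    separated: bool

    def predict_proba(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        z = self.coef[0] + X @ self.coef[1:]
        return 1.0 / (1.0 + np.exp(-z))


def logistic_fit(
    X, labels, feature_names: tuple[str, ...] | None = None, max_iter: int = 50
) -> LogisticModel:
    """Maximum-likelihood logistic regression via IRLS.

    Mirrors the published models: one or two biomarkers scoring the
    probability of multichannel block.  Complete separation is reported as
    a warning (iterations capped), not a crash.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 2:
        X = X.T
    y = _binary_labels(labels)
    if X.shape[0] != y.size:
        raise ValueError("X rows must match labels")
    n, p = X.shape
    names = feature_names or tuple(f"x{i+1}" for i in range(p))
    A = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    converged = separated = False
    for _ in range(max_iter):
        eta = A @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        AtW = A.T * w
        try:
            new = np.linalg.solve(AtW @ A, AtW @ z)
        except np.linalg.LinAlgError:
            new = np.linalg.lstsq(AtW @ A, AtW @ z, rcond=None)[0]
        step = np.max(np.abs(new - beta))
        beta = new
        if np.max(np.abs(beta)) > 30.0 / max(np.std(X, axis=0).min(), 1e-12):
            separated = True
            break
        if step < 1e-10:
            converged = True
            break
    if separated:
        warnings.warn(
            "complete or quasi-complete separation: coefficients capped",
            RuntimeWarning,
            stacklevel=2,
        )
    return LogisticModel(tuple(names), beta, converged, separated)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    auc: float
    ci95: tuple[float, float] | None
    best_sensitivity: float
    best_specificity: float
    features: tuple[str, ...] = ()


def _auc_mann_whitney(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as the normalized rank-sum of positive-class scores (ties 1/2)."""
    ranks = stats.rankdata(scores)
    n1 = int(y.sum())
    n0 = y.size - n1
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def roc_auc(scores, labels, features: tuple[str, ...] = ()) -> RocResult:
    """AUC plus the operating point maximizing sensitivity + specificity."""
    scores = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    auc = _auc_mann_whitney(scores, y)
    # sweep thresholds at the distinct scores (predict positive if >= thr)
    order = np.argsort(-scores, kind="mergesort")
    ys = y[order]
    ss = scores[order]
    tp = np.cumsum(ys)
    fp = np.cumsum(1 - ys)
    n1, n0 = tp[-1], fp[-1]
    last = np.flatnonzero(np.diff(ss) != 0)
    idx = np.concatenate((last, [ss.size - 1]))
    sens = tp[idx] / n1
    spec = 1 - fp[idx] / n0
    j = int(np.argmax(sens + spec))
    return RocResult(auc, None, float(sens[j]), float(spec[j]), features)


def auc_bootstrap_ci(
    scores, labels, n_boot: int = 2000, seed: int | np.random.SeedSequence = 0
) -> tuple[float, float]:
    """Percentile 95% CI of AUC from stratified bootstrap resampling."""
    if n_boot < 100:
        warnings.warn("fewer than 100 bootstrap replicates", RuntimeWarning, stacklevel=2)
    scores = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    pos = scores[y == 1]
    neg = scores[y == 0]
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least 2 members per class")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ps = rng.choice(pos, pos.size, replace=True)
        ns = rng.choice(neg, neg.size, replace=True)
        s = np.concatenate([ps, ns])
        yy = np.concatenate([np.ones(ps.size, dtype=int), np.zeros(ns.size, dtype=int)])
        aucs[b] = _auc_mann_whitney(s, yy)
    return (float(np.percentile(aucs, 2.5)), float(np.percentile(aucs, 97.5)))


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / neg.size for p in pos])
    v01 = np.array([(np.sum(pos > n) + 0.5 * np.sum(pos == n)) / pos.size for n in neg])
    return v10, v01


def delong_test(scores_a, scores_b, labels) -> dict[str, float]:
    """DeLong's test for the difference of two paired (same-row) AUCs."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("scores must be paired on identical rows")
    y = _binary_labels(labels)
    v10a, v01a = _placements(a, y)
    v10b, v01b = _placements(b, y)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 1e-16:
        p = 1.0 if abs(diff) < 1e-12 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return {"auc_a": auc_a, "auc_b": auc_b, "p_value": p}


# ---------------------------------------------------------------------------
# Decision rule and learner
# ---------------------------------------------------------------------------


@dataclass
class TreeRule:
    """Two-threshold rule on (ddJ-Tpeakc, ddQTc).

    ddJ-Tpeakc > threshold -> hERG (early repolarization still prolonged);
    otherwise ddQTc <= threshold -> multichannel; otherwise inconclusive.
    The defaults are the published thresholds.
    """

    jtpeakc_threshold_ms: float = 9.0
    qtc_threshold_ms: float = 29.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.jtpeakc_threshold_ms) and np.isfinite(self.qtc_threshold_ms)):
            raise ValueError("thresholds must be finite")


def tree_classify(ddjtpeakc_ms, ddqtc_ms, rule: TreeRule | None = None):
    """Classify placebo-corrected changes; scalar or vectorized."""
    rule = rule or TreeRule()
    jt = np.asarray(ddjtpeakc_ms, dtype=float)
    qt = np.asarray(ddqtc_ms, dtype=float)
    if not (np.all(np.isfinite(jt)) and np.all(np.isfinite(qt))):
        raise ValueError("inputs must be finite")
    out = np.where(
        jt > rule.jtpeakc_threshold_ms,
        NEGATIVE_CLASS,
        np.where(qt <= rule.qtc_threshold_ms, POSITIVE_CLASS, INCONCLUSIVE),
    )
    return out.item() if out.ndim == 0 else out


def _entropy(counts: np.ndarray) -> float:
    tot = counts.sum()
    if tot == 0:
        return 0.0
    p = counts[counts > 0] / tot
    return float(-(p * np.log2(p)).sum())


def gain_ratio(values: np.ndarray, y: np.ndarray, threshold: float) -> float:
    """C4.5 gain ratio of the binary split ``value <= threshold``."""
    left = values <= threshold
    n = y.size
    nl, nr = int(left.sum()), int(n - left.sum())
    if nl == 0 or nr == 0:
        return 0.0
    parent = _entropy(np.bincount(y, minlength=2))
    child = (
        nl / n * _entropy(np.bincount(y[left], minlength=2))
        + nr / n * _entropy(np.bincount(y[~left], minlength=2))
    )
    gain = parent - child
    split_info = _entropy(np.array([nl, nr]))
    return gain / split_info if split_info > 0 else 0.0


@dataclass
class _Node:
    feature: int | None = None
    threshold: float | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None
    label: str | None = None


@dataclass
class LearnedTree:
    root: _Node
    feature_names: tuple[str, ...]
    cv_metrics: dict[str, float] = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = []
        for row in X:
            node = self.root
            while node.label is None:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out.append(node.label)
        return np.array(out)

    def as_rule(self) -> TreeRule | None:
        """Collapse to a TreeRule when the learned shape matches the fixed
        two-threshold structure (first split on feature 0, second on 1)."""
        r = self.root
        if r.feature == 0 and r.left is not None and r.left.feature == 1:
            return TreeRule(
                jtpeakc_threshold_ms=float(r.threshold),
                qtc_threshold_ms=float(r.left.threshold),
            )
        return None


def _info_gain(values: np.ndarray, y: np.ndarray, threshold: float) -> float:
    left = values <= threshold
    n = y.size
    nl = int(left.sum())
    if nl == 0 or nl == n:
        return 0.0
    parent = _entropy(np.bincount(y, minlength=2))
    child = (
        nl / n * _entropy(np.bincount(y[left], minlength=2))
        + (n - nl) / n * _entropy(np.bincount(y[~left], minlength=2))
    )
    return parent - child


def _best_split(X: np.ndarray, y: np.ndarray, min_leaf: int = 2):
    """Best (gain_ratio, feature, threshold) among candidate midpoints.

    Follows the C4.5 guards against the gain-ratio bias toward highly
    unbalanced splits: each side must hold at least ``min_leaf`` rows, and
    only candidates with at least the average positive information gain
    compete on gain ratio.
    """
    candidates = []  # (gain, gain_ratio, feature, threshold)
    for f in range(X.shape[1]):
        vals = np.unique(X[:, f])
        if vals.size < 2:
            continue
        mids = (vals[:-1] + vals[1:]) / 2
        for thr in mids:
            nl = int(np.sum(X[:, f] <= thr))
            if nl < min_leaf or y.size - nl < min_leaf:
                continue
            g = _info_gain(X[:, f], y, thr)
            if g > 1e-12:
                candidates.append((g, gain_ratio(X[:, f], y, thr), f, float(thr)))
    if not candidates:
        return (0.0, None, None)
    avg_gain = np.mean([c[0] for c in candidates])
    eligible = [c for c in candidates if c[0] >= avg_gain - 1e-12]
    g, gr, f, thr = max(eligible, key=lambda c: c[1])
    return (gr, f, thr)


def _leaf_label(y: np.ndarray, min_purity: float) -> str:
    counts = np.bincount(y, minlength=2)
    purity = counts.max() / counts.sum()
    if purity < min_purity:
        return INCONCLUSIVE
    return POSITIVE_CLASS if counts[1] >= counts[0] else NEGATIVE_CLASS


def _grow(X, y, depth, max_depth, min_samples, min_purity, min_leaf) -> _Node:
    if depth >= max_depth or y.size < min_samples or len(np.unique(y)) == 1:
        return _Node(label=_leaf_label(y, min_purity))
    g, f, thr = _best_split(X, y, min_leaf)
    if f is None or g <= 0:
        return _Node(label=_leaf_label(y, min_purity))
    left = X[:, f] <= thr
    return _Node(
        feature=f,
        threshold=thr,
        left=_grow(X[left], y[left], depth + 1, max_depth, min_samples, min_purity, min_leaf),
        right=_grow(X[~left], y[~left], depth + 1, max_depth, min_samples, min_purity, min_leaf),
    )


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator):
    assign = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assign[idx] = np.arange(idx.size) % folds
    return assign


def learn_tree(
    X,
    labels,
    feature_names: tuple[str, ...] = ("ddjtpeakc_ms", "ddqtc_ms"),
    max_depth: int = 2,
    folds: int = 10,
    seed: int = 0,
    min_samples: int = 10,
    min_purity: float = 0.55,
    min_leaf_frac: float = 0.05,
) -> LearnedTree:
    """Greedy depth-<=2 gain-ratio threshold tree with stratified CV.

    A compact stand-in for a full C4.5 learner: binary splits at
    observed-value midpoints maximizing gain ratio (with the C4.5
    average-gain guard and a minimum leaf occupancy of ``min_leaf_frac`` of
    the training rows), majority leaves with an "inconclusive" label when
    leaf purity falls below ``min_purity``, and seeded stratified
    ``folds``-fold cross-validated accuracy, sensitivity and specificity
    (inconclusive predictions count as errors).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = _binary_labels(labels)
    if min(np.bincount(y)) < folds:
        raise ValueError("need at least `folds` rows per class")
    rng = np.random.default_rng(seed)
    min_leaf = max(2, int(round(min_leaf_frac * y.size)))
    assign = _stratified_folds(y, folds, rng)
    preds = np.empty(y.size, dtype=object)
    for k in range(folds):
        tr = assign != k
        tree = LearnedTree(
            _grow(X[tr], y[tr], 0, max_depth, min_samples, min_purity, min_leaf),
            feature_names,
        )
        preds[~tr] = tree.predict(X[~tr])
    labels_arr = np.where(y == 1, POSITIVE_CLASS, NEGATIVE_CLASS)
    cv = evaluate_classifier(preds, labels_arr, n_boot=0)
    cv.pop("ci95", None)
    full = LearnedTree(
        _grow(X, y, 0, max_depth, min_samples, min_purity, min_leaf),
        feature_names,
        cv_metrics=cv,
    )
    return full


def evaluate_classifier(
    predictions,
    labels,
    n_boot: int = 2000,
    seed: int | np.random.SeedSequence = 0,
    exclude_inconclusive: bool = False,
) -> dict:
    """Accuracy/sensitivity/specificity with a stratified bootstrap CI.

    By default "inconclusive" predictions count as misclassifications; with
    ``exclude_inconclusive`` metrics are recomputed on conclusive rows only.
    """
    preds = np.asarray(predictions, dtype=object)
    labs = np.asarray(labels, dtype=object)
    if preds.shape != labs.shape:
        raise ValueError("predictions and labels must align")
    if exclude_inconclusive:
        keep = preds != INCONCLUSIVE
        preds, labs = preds[keep], labs[keep]
        if preds.size == 0:
            raise ValueError("no conclusive predictions")

    def metrics(p, l):
        correct = p == l
        acc = float(np.mean(correct))
        pos = l == POSITIVE_CLASS
        neg = l == NEGATIVE_CLASS
        sens = float(np.mean(correct[pos])) if pos.any() else np.nan
        spec = float(np.mean(correct[neg])) if neg.any() else np.nan
        return acc, sens, spec

    acc, sens, spec = metrics(preds, labs)
    out = {"accuracy": acc, "sensitivity": sens, "specificity": spec, "n": int(preds.size)}
    if n_boot:
        rng = np.random.default_rng(seed)
        cls_idx = [np.flatnonzero(labs == c) for c in np.unique(labs)]
        accs = np.empty(n_boot)
        for b in range(n_boot):
            idx = np.concatenate([rng.choice(ix, ix.size, replace=True) for ix in cls_idx])
            accs[b] = metrics(preds[idx], labs[idx])[0]
        out["ci95"] = (float(np.percentile(accs, 2.5)), float(np.percentile(accs, 97.5)))
    return out
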