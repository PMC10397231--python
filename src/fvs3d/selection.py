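"""Feature selection and leave-one-out classification of hemodynamic features.

Three selection procedures are provided: a two-sample t-test filter at a fixed
significance level, a one-way ANOVA F-test filter whose p-value threshold is
scanned over a grid and scored by leave-one-out accuracy, and a forward
best-first subset search.  A battery of standard classifiers (XGBoost, SVM,
nearest neighbour, decision tree, naive Bayes, logistic regression, random
forest) is evaluated with leave-one-out cross-validation.

By default selection is performed once on the full table and LOOCV measures
the classifier only (the protocol used with small cohorts); a nested mode that
re-selects inside every LOOCV fold is available and avoids the optimism of the
default.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier


@dataclass
class FeatureTable:
    """Subjects x named features plus a binary label per subject."""

    features: pd.DataFrame
    labels: pd.Series

    def __post_init__(self):
        if self.features.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing values")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")

    @property
    def n_subjects(self) -> int:
        return len(self.features)

    def X(self, names=None) -> np.ndarray:
        df = self.features if names is None else self.features[list(names)]
        return df.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=int)

    def to_csv(self, features_path, labels_path) -> None:
        self.features.to_csv(features_path)
        self.labels.rename("label").to_csv(labels_path)

    @classmethod
    def from_csv(cls, features_path, labels_path) -> "FeatureTable":
        feats = pd.read_csv(features_path, index_col=0)
        labels = pd.read_csv(labels_path, index_col=0)["label"]
        return cls(feats, labels)


@dataclass
class SelectionResult:
    method: str
    selected: list[str]
    stats: pd.DataFrame | None = None        # per-feature statistic / p-value
    accuracies: dict[str, float] = field(default_factory=dict)
    details: dict = field(default_factory=dict)


def make_classifiers(seed: int = 0) -> dict:
    """The classifier battery with library-default hyperparameters, seeded."""
    from xgboost import XGBClassifier

    return {
        "xgboost": XGBClassifier(random_state=seed, n_estimators=50,
                                 verbosity=0, eval_metric="logloss"),
        "svm": SVC(random_state=seed),
        "nearest_neighbor": KNeighborsClassifier(),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "naive_bayes": GaussianNB(),
        "logistic_regression": LogisticRegression(max_iter=1000,
                                                  random_state=seed),
        "random_forest": RandomForestClassifier(random_state=seed,
                                                n_estimators=100),
    }


def loocv_accuracy(clf, X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out: fit on n-1 subjects, predict the held-out one."""
    from sklearn.base import clone

    n = len(y)
    if n < 2 or X.shape[1] == 0:
        raise ValueError("LOOCV needs >= 2 subjects and >= 1 feature")
    correct = 0
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        if len(np.unique(y[tr])) < 2:
            # degenerate fold: predict the majority class of the training fold
            pred = int(np.bincount(y[tr]).argmax())
        else:
            m = clone(clf)
            m.fit(X[tr], y[tr])
            pred = int(m.predict(X[i][None, :])[0])
        correct += pred == y[i]
    return correct / n


def _check_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    for c in (0, 1):
        if (y == c).sum() < 2:
            raise ValueError(f"need >= 2 subjects in class {c}")


def ttest_filter(table: FeatureTable, alpha: float = 0.05) -> SelectionResult:
    """Two-sample equal-variance two-sided t-test per feature; keep p < alpha.

    Features that are constant within the table are excluded with a warning
    (their test statistic is undefined).
    """
    y = table.y
    _check_classes(y)
    X = table.X()
    names = list(table.features.columns)
    const = X.std(axis=0) == 0
    if const.any():
        warnings.warn(f"{const.sum()} constant features excluded from t-test")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(X[y == 0], X[y == 1], equal_var=True, axis=0)
    p = np.where(const, np.nan, p)
    keep = np.nan_to_num(p, nan=1.0) < alpha
    stats_df = pd.DataFrame({"feature": names, "statistic": t, "p_value": p})
    return SelectionResult("ttest_filter",
                           [n for n, k in zip(names, keep) if k],
                           stats=stats_df, details={"alpha": alpha})


def _f_test_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        f, p = stats.f_oneway(X[y == 0], X[y == 1], axis=0)
    return np.nan_to_num(p, nan=1.0)


def ftest_threshold_scan(table: FeatureTable, classifier=None,
                         thresholds: np.ndarray | None = None,
                         seed: int = 0) -> SelectionResult:
    """Scan a grid of F-test p-value thresholds; keep the subset with the
    best LOOCV accuracy (ties: smaller subset, then smaller threshold)."""
    if classifier is None:
        classifier = SVC(random_state=seed)
    if thresholds is None:
        thresholds = np.arange(0.001, 0.1005, 0.001)
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    if thresholds.size == 0:
        raise ValueError("threshold grid is empty")
    y = table.y
    _check_classes(y)
    X = table.X()
    names = np.asarray(table.features.columns)
    p = _f_test_pvalues(X, y)

    best = None  # (-acc, subset_size, threshold, mask)
    trace = []
    seen_sizes = set()
    for th in thresholds:
        mask = p < th
        size = int(mask.sum())
        if size == 0 or size in seen_sizes:
            continue
        seen_sizes.add(size)
        acc = loocv_accuracy(classifier, X[:, mask], y)
        trace.append((float(th), size, acc))
        key = (-acc, size, th)
        if best is None or key < best[0]:
            best = (key, mask, float(th), acc)
    if best is None:
        raise ValueError("no threshold in the grid selects any feature")
    _, mask, th, acc = best
    return SelectionResult(
        "ftest_threshold_scan", list(names[mask]),
        stats=pd.DataFrame({"feature": names, "p_value": p}),
        accuracies={"scan_classifier": acc},
        details={"threshold": th, "trace": trace})


def best_first_search(table: FeatureTable, classifier=None,
                      max_no_improve: int = 5, seed: int = 0,
                      max_expansions: int = 200) -> SelectionResult:
    """Forward best-first subset search scored by LOOCV accuracy.

    A priority queue of candidate subsets is keyed by accuracy; the best
    unexpanded subset is expanded by adding each absent feature.  The search
    stops after ``max_no_improve`` consecutive expansions that fail to
    improve the incumbent.  Deterministic: ties prefer smaller subsets in
    feature order.
    """
    if classifier is None:
        classifier = SVC(random_state=seed)
    y = table.y
    _check_classes(y)
    X = table.X()
    names = list(table.features.columns)
    nfeat = len(names)
    if nfeat < 1:
        raise ValueError("need at least one feature")

    majority = max(np.bincount(y)) / len(y)   # empty-subset baseline

    def score(mask: frozenset) -> float:
        cols = sorted(mask)
        return loocv_accuracy(classifier, X[:, cols], y)

    start: frozenset = frozenset()
    incumbent, inc_acc = start, majority
    # heap entries: (-acc, subset_size, order_key, mask)
    pq = [(-inc_acc, 0, (), start)]
    expanded: set[frozenset] = set()
    scored: dict[frozenset, float] = {start: inc_acc}
    no_improve = 0
    n_exp = 0
    while pq and no_improve < max_no_improve and n_exp < max_expansions:
        _, _, _, cur = heapq.heappop(pq)
        if cur in expanded:
            continue
        expanded.add(cur)
        n_exp += 1
        improved = False
        for j in range(nfeat):
            if j in cur:
                continue
            child = cur | {j}
            if child in scored:
                continue
            acc = score(child)
            scored[child] = acc
            heapq.heappush(pq, (-acc, len(child), tuple(sorted(child)), child))
            if acc > inc_acc:
                incumbent, inc_acc = child, acc
                improved = True
        no_improve = 0 if improved else no_improve + 1

    selected = [names[j] for j in sorted(incumbent)]
    return SelectionResult("best_first_search", selected,
                           accuracies={"search_classifier": inc_acc},
                           details={"n_subsets_scored": len(scored),
                                    "baseline": majority})


def evaluate_classifiers(table: FeatureTable, selection: SelectionResult,
                         classifiers: dict | None = None,
                         seed: int = 0) -> dict[str, float | None]:
    """LOOCV accuracy of every classifier on the selected features.

    A classifier failure is recorded as ``None`` rather than dropped.
    """
    if not selection.selected:
        raise ValueError("selection is empty")
    classifiers = classifiers or make_classifiers(seed)
    X = table.X(selection.selected)
    y = table.y
    out: dict[str, float | None] = {}
    for name, clf in classifiers.items():
        try:
            out[name] = loocv_accuracy(clf, X, y)
        except Exception as exc:  # noqa: BLE001 - recorded, not silenced
            warnings.warn(f"classifier {name} failed: {exc}")
            out[name] = None
    return out


def nested_loocv_accuracy(table: FeatureTable, select_fn, classifier,
                          seed: int = 0) -> float:
    """LOOCV with feature selection re-run inside every fold (no peeking)."""
    from sklearn.base import clone

    y = table.y
    n = len(y)
    correct = 0
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        sub = FeatureTable(table.features.iloc[tr], table.labels.iloc[tr])
        sel = select_fn(sub)
        cols = sel.selected if sel.selected else list(table.features.columns)
        m = clone(classifier)
        m.fit(sub.features[cols].to_numpy(float), y[tr])
        pred = int(m.predict(table.features[cols].to_numpy(float)[~tr])[0])
        correct += pred == y[i]
    return correct / n
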