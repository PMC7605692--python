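"""Wear/non-wear decision trees with leave-one-subject-out evaluation.

The classifier is a CART binary tree (Gini criterion, cost-complexity
pruned).  The pruning strength is an rpart-style *relative* complexity
parameter ``cp``: internally it is mapped to scikit-learn's absolute
``ccp_alpha`` as ``cp * gini(root)``, so ``cp`` is comparable across
training sets of different class balance.  ``cp`` is tuned by inner
stratified k-fold cross-validation maximizing ROC AUC over a logarithmic
grid, with ties broken toward the largest ``cp`` (strongest pruning).

Evaluation uses leave-one-out cross-validation *by participant*: every fold
tunes and fits on all other participants and predicts the held-out one, so
no within-subject leakage can occur.  Non-wear is the positive class
throughout.

Two entry points are provided: plain functions (:func:`tune_cp`,
:func:`fit_tree`, :func:`predict_minutes`, :func:`loocv`) and a
model/results pair (:class:`WearTreeModel` -> :class:`WearTreeResults` /
:class:`LOOCVResults`) for interactive use.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from . import metrics as _metrics
from .features import SITES, pivot_sites

logger = logging.getLogger(__name__)

NONWEAR, WEAR = "nonwear", "wear"
SINGLE_SITE_PREDICTORS = ("incl_x", "incl_y", "incl_z", "cv4_x", "cv4_y", "cv4_z")


def default_predictors(site_mode: str) -> list[str]:
    """The final predictor set: per-axis inclination angles and 4-minute CVs."""
    if site_mode in SITES:
        return list(SINGLE_SITE_PREDICTORS)
    if site_mode == "combined":
        return [f"{site}_{p}" for site in SITES for p in SINGLE_SITE_PREDICTORS]
    raise ValueError(f"site_mode must be 'hip', 'ankle' or 'combined', got {site_mode!r}")


def default_cp_grid(low: float = 1e-5, high: float = 1e-1, size: int = 50) -> np.ndarray:
    """50 logarithmically spaced complexity-parameter values in [1e-5, 1e-1]."""
    return np.geomspace(low, high, size)


@dataclass
class ModelSpec:
    """Configuration of one classifier (site mode, predictors, tuning grid)."""

    site_mode: str = "combined"
    predictors: Sequence[str] | None = None
    cp_grid: np.ndarray | None = None
    inner_folds: int = 10
    tuning_metric: str = "roc_auc"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.predictors is None:
            self.predictors = default_predictors(self.site_mode)
        self.predictors = list(self.predictors)
        if not self.predictors:
            raise ValueError("predictors must be non-empty")
        if self.cp_grid is None:
            self.cp_grid = default_cp_grid()
        self.cp_grid = np.asarray(self.cp_grid, dtype=float)
        if np.any(self.cp_grid <= 0) or np.any(self.cp_grid >= 1):
            raise ValueError("cp grid values must lie in (0, 1)")
        if len(self.cp_grid) > 1 and np.any(np.diff(self.cp_grid) <= 0):
            raise ValueError("cp grid must be strictly increasing")


def prepare_table(feature_table: pd.DataFrame, site_mode: str) -> pd.DataFrame:
    """Select one site (long table) or pivot both sites wide for 'combined'."""
    if site_mode in SITES:
        out = feature_table[feature_table["site"] == site_mode].copy()
        if not len(out):
            raise ValueError(f"feature table has no rows for site {site_mode!r}")
        return out
    if site_mode == "combined":
        return pivot_sites(feature_table)
    raise ValueError(f"unknown site_mode {site_mode!r}")


# ---------------------------------------------------------------------------
# tree representation


@dataclass
class TreeNode:
    """Internal split (feature/threshold) or leaf (feature is None)."""

    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    klass: str | None = None
    p_nonwear: float | None = None
    n: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"class": self.klass, "p_nonwear": self.p_nonwear, "n": self.n}
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "n": self.n,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @staticmethod
    def from_dict(d: dict) -> "TreeNode":
        if "feature" not in d:
            return TreeNode(klass=d["class"], p_nonwear=d["p_nonwear"], n=d["n"])
        return TreeNode(
            feature=d["feature"],
            threshold=d["threshold"],
            n=d["n"],
            left=TreeNode.from_dict(d["left"]),
            right=TreeNode.from_dict(d["right"]),
        )


@dataclass
class TrainedTree:
    """A fitted, pruned wear/non-wear tree with its own traversal.

    Independent of scikit-learn once built; serializes losslessly to JSON.
    """

    root: TreeNode
    predictors: list[str]
    selected_cp: float
    training_participants: list[str] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        def count(node: TreeNode) -> int:
            return 1 if node.is_leaf else count(node.left) + count(node.right)

        return count(self.root)

    def predict_frame(self, table: pd.DataFrame) -> pd.DataFrame:
        """Per-row label and non-wear probability.

        Rows with any missing predictor get a missing label (they are
        excluded from metrics downstream).  Unknown predictor columns raise.
        """
        missing_cols = [p for p in self.predictors if p not in table.columns]
        if missing_cols:
            raise KeyError(f"table lacks predictor column(s) {missing_cols}")
        X = table[self.predictors].to_numpy(dtype=float)
        ok = np.all(np.isfinite(X), axis=1)
        labels = np.full(len(table), None, dtype=object)
        p_nw = np.full(len(table), np.nan)

        col = {p: i for i, p in enumerate(self.predictors)}

        def walk(node: TreeNode, idx: np.ndarray) -> None:
            if not idx.size:
                return
            if node.is_leaf:
                labels[idx] = node.klass
                p_nw[idx] = node.p_nonwear
                return
            go_left = X[idx, col[node.feature]] <= node.threshold
            walk(node.left, idx[go_left])
            walk(node.right, idx[~go_left])

        walk(self.root, np.flatnonzero(ok))
        return pd.DataFrame({"label": labels, "p_nonwear": p_nw}, index=table.index)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "infantwear-tree",
            "version": 1,
            "predictors": self.predictors,
            "selected_cp": self.selected_cp,
            "training_participants": self.training_participants,
            "root": self.root.to_dict(),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    @staticmethod
    def from_dict(d: dict) -> "TrainedTree":
        return TrainedTree(
            root=TreeNode.from_dict(d["root"]),
            predictors=list(d["predictors"]),
            selected_cp=float(d["selected_cp"]),
            training_participants=list(d.get("training_participants", [])),
        )

    @staticmethod
    def from_json(s: str) -> "TrainedTree":
        return TrainedTree.from_dict(json.loads(s))

    def render(self) -> str:
        """Human-readable indented rendering of the tree."""
        lines: list[str] = []

        def walk(node: TreeNode, depth: int, prefix: str) -> None:
            pad = "  " * depth
            if node.is_leaf:
                lines.append(
                    f"{pad}{prefix}-> {node.klass} (p_nonwear={node.p_nonwear:.3f}, n={node.n})"
                )
            else:
                lines.append(f"{pad}{prefix}{node.feature} <= {node.threshold:.4g} (n={node.n})")
                walk(node.left, depth + 1, "[yes] ")
                walk(node.right, depth + 1, "[no]  ")

        walk(self.root, 0, "")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# fitting and tuning


def _training_arrays(
    table: pd.DataFrame, predictors: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, int]:
    missing_cols = [p for p in predictors if p not in table.columns]
    if missing_cols:
        raise KeyError(f"table lacks predictor column(s) {missing_cols}")
    sub = table[list(predictors) + ["wear"]]
    X = sub[list(predictors)].to_numpy(dtype=float)
    y = sub["wear"].to_numpy(dtype=object)
    ok = np.all(np.isfinite(X), axis=1) & pd.notna(y)
    n_excluded = int(len(sub) - ok.sum())
    if n_excluded:
        logger.info("excluded %d row(s) with missing predictors or labels", n_excluded)
    return X[ok], y[ok].astype(str), n_excluded


def _fit_sklearn(X: np.ndarray, y: np.ndarray, cp: float, seed: int) -> DecisionTreeClassifier:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data contains a single class; both wear and non-wear required")
    p = counts / counts.sum()
    root_gini = 1.0 - float(np.sum(p**2))
    clf = DecisionTreeClassifier(
        criterion="gini", ccp_alpha=cp * root_gini, random_state=seed
    )
    clf.fit(X, y)
    return clf


def _extract(clf: DecisionTreeClassifier, predictors: Sequence[str]) -> TreeNode:
    t = clf.tree_
    classes = list(clf.classes_)
    nw = classes.index(NONWEAR) if NONWEAR in classes else None

    def build(i: int) -> TreeNode:
        n = int(t.n_node_samples[i])
        if t.children_left[i] == -1:
            value = np.asarray(t.value[i][0], dtype=float)
            probs = value / value.sum() if value.sum() else value
            klass = classes[int(np.argmax(probs))]
            p_nonwear = float(probs[nw]) if nw is not None else 0.0
            return TreeNode(klass=klass, p_nonwear=p_nonwear, n=n)
        return TreeNode(
            feature=predictors[int(t.feature[i])],
            threshold=float(t.threshold[i]),
            n=n,
            left=build(int(t.children_left[i])),
            right=build(int(t.children_right[i])),
        )

    return build(0)


def fit_tree(
    train_table: pd.DataFrame,
    predictors: Sequence[str],
    cp: float,
    seed: int = 0,
) -> TrainedTree:
    """Grow and cost-complexity prune a CART tree at relative penalty ``cp``.

    Rows with missing predictor values or labels are excluded (count
    logged).  Deterministic given table, predictors, cp and seed.
    """
    X, y, _ = _training_arrays(train_table, predictors)
    if not len(X):
        raise ValueError("no training rows remain after excluding missing values")
    clf = _fit_sklearn(X, y, cp, seed)
    participants = (
        sorted(train_table["participant_id"].dropna().unique().tolist())
        if "participant_id" in train_table.columns
        else []
    )
    return TrainedTree(
        root=_extract(clf, predictors),
        predictors=list(predictors),
        selected_cp=float(cp),
        training_participants=participants,
    )


def tune_cp(train_table: pd.DataFrame, spec: ModelSpec) -> float:
    """Select cp by inner stratified k-fold CV maximizing mean ROC AUC.

    Ties (within 1e-12 of the best mean AUC) are broken toward the largest
    cp, i.e. the most strongly pruned tree.
    """
    X, y, _ = _training_arrays(train_table, spec.predictors)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("tuning requires both classes in the training data")
    n_splits = int(min(spec.inner_folds, counts.min()))
    if n_splits < 2:
        raise ValueError("too few minutes of the minority class for inner cross-validation")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=spec.seed)
    splits = list(skf.split(X, y))

    mean_aucs = np.full(len(spec.cp_grid), np.nan)
    for j, cp in enumerate(spec.cp_grid):
        aucs = []
        for tr, te in splits:
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                continue
            clf = _fit_sklearn(X[tr], y[tr], cp, spec.seed)
            nw_idx = list(clf.classes_).index(NONWEAR)
            p = clf.predict_proba(X[te])[:, nw_idx]
            aucs.append(roc_auc_score(y[te] == NONWEAR, p))
        if aucs:
            mean_aucs[j] = float(np.mean(aucs))
    if np.all(np.isnan(mean_aucs)):
        raise ValueError("inner cross-validation produced no valid folds")
    best = np.nanmax(mean_aucs)
    tied = np.flatnonzero(mean_aucs >= best - 1e-12)
    return float(spec.cp_grid[tied[-1]])


def predict_minutes(tree: TrainedTree, table: pd.DataFrame) -> pd.DataFrame:
    """Per-minute predicted labels and non-wear probabilities.

    Rows with missing predictors receive a missing label.
    """
    return tree.predict_frame(table)


@dataclass
class FoldResult:
    """One LOOCV fold: held-out participant, paired labels, and the tree."""

    participant: str
    frame: pd.DataFrame  # minute_start, y_true, y_pred, p_nonwear
    selected_cp: float
    tree: TrainedTree
    n_excluded: int = 0

    @property
    def confusion(self) -> "_metrics.ConfusionSummary":
        paired = self.frame.dropna(subset=["y_true", "y_pred"])
        return _metrics.confusion_metrics(paired["y_pred"], paired["y_true"])


def loocv(feature_table: pd.DataFrame, spec: ModelSpec, prepared: bool = False) -> list[FoldResult]:
    """Leave-one-participant-out evaluation of a model specification.

    For each participant: tune cp and fit on all other participants, then
    predict the held-out participant's minutes.  Folds are keyed by
    participant id, so row order is irrelevant.  A held-out participant
    with no labeled minutes is skipped with a warning.
    """
    table = feature_table if prepared else prepare_table(feature_table, spec.site_mode)
    participants = sorted(table["participant_id"].dropna().unique().tolist())
    if len(participants) < 2:
        raise ValueError("LOOCV requires at least two participants")

    results: list[FoldResult] = []
    for pid in participants:
        held = table[table["participant_id"] == pid]
        train = table[table["participant_id"] != pid]
        if held["wear"].notna().sum() == 0:
            warnings.warn(f"participant {pid!r} has no labeled minutes; fold skipped", stacklevel=2)
            continue
        cp = tune_cp(train, spec)
        tree = fit_tree(train, spec.predictors, cp, seed=spec.seed)
        pred = tree.predict_frame(held)
        labeled = held["wear"].notna()
        frame = pd.DataFrame(
            {
                "participant_id": pid,
                "minute_start": held["minute_start"].to_numpy(),
                "y_true": held["wear"].to_numpy(object),
                "y_pred": pred["label"].to_numpy(object),
                "p_nonwear": pred["p_nonwear"].to_numpy(),
            }
        )
        n_excluded = int((labeled & pred["label"].isna()).sum())
        results.append(
            FoldResult(participant=pid, frame=frame, selected_cp=cp, tree=tree, n_excluded=n_excluded)
        )
    return results


# ---------------------------------------------------------------------------
# model / results API


class WearTreeModel:
    """Wear/non-wear CART model bound to a minute-level feature table.

    Parameters
    ----------
    feature_table
        Long feature table (one row per participant x site x minute) as
        produced by :func:`infantwear.features.build_feature_table`.
    site_mode
        'hip', 'ankle' (single-site) or 'combined' (both sites' predictors).
    predictors, cp_grid, inner_folds, seed
        See :class:`ModelSpec`; defaults follow the final published models
        (per-axis inclination angles + 4-minute per-axis CVs, 50 log-spaced
        cp values in [1e-5, 1e-1], 10 inner folds).

    Examples
    --------
    >>> model = WearTreeModel(features, site_mode="ankle", seed=1)
    >>> res = model.fit()          # tunes cp, fits on all participants
    >>> cv = model.loocv()         # leave-one-participant-out evaluation
    >>> cv.summary()               # mean and (min, max) of each metric
    """

    def __init__(
        self,
        feature_table: pd.DataFrame,
        site_mode: str = "combined",
        predictors: Sequence[str] | None = None,
        cp_grid: np.ndarray | None = None,
        inner_folds: int = 10,
        seed: int = 0,
    ) -> None:
        self.spec = ModelSpec(
            site_mode=site_mode,
            predictors=predictors,
            cp_grid=cp_grid,
            inner_folds=inner_folds,
            seed=seed,
        )
        self.feature_table = feature_table
        self.table = prepare_table(feature_table, site_mode)

    @classmethod
    def from_features(cls, feature_table: pd.DataFrame, **kwargs) -> "WearTreeModel":
        return cls(feature_table, **kwargs)

    def tune(self) -> float:
        return tune_cp(self.table, self.spec)

    def fit(self, cp: float | None = None) -> "WearTreeResults":
        """Fit on all participants; tunes cp by inner CV when not given."""
        if cp is None:
            cp = self.tune()
        tree = fit_tree(self.table, self.spec.predictors, cp, seed=self.spec.seed)
        return WearTreeResults(self, tree)

    def loocv(self) -> "LOOCVResults":
        return LOOCVResults(self, loocv(self.table, self.spec, prepared=True))


class WearTreeResults:
    """A fitted tree plus convenience prediction/summary methods."""

    def __init__(self, model: WearTreeModel, tree: TrainedTree) -> None:
        self.model = model
        self.tree = tree
        self.selected_cp = tree.selected_cp

    def predict(self, table: pd.DataFrame | None = None) -> pd.DataFrame:
        return self.tree.predict_frame(self.model.table if table is None else table)

    def summary(self) -> str:
        pred = self.predict()
        paired = pd.DataFrame(
            {"y_true": self.model.table["wear"].to_numpy(object), "y_pred": pred["label"]}
        ).dropna()
        cm = _metrics.confusion_metrics(paired["y_pred"], paired["y_true"])
        head = (
            f"WearTreeResults: site_mode={self.model.spec.site_mode}, "
            f"cp={self.selected_cp:.3g}, leaves={self.tree.n_leaves}\n"
            f"training accuracy={cm.accuracy:.3f} sensitivity={cm.sensitivity:.3f} "
            f"specificity={cm.specificity:.3f} F1={cm.f1:.3f}\n"
        )
        return head + self.tree.render()


class LOOCVResults:
    """Leave-one-participant-out folds with Table-2-style summaries."""

    def __init__(self, model: WearTreeModel, folds: list[FoldResult]) -> None:
        self.model = model
        self.folds = folds

    def predictions(self) -> pd.DataFrame:
        """Held-out predictions for every participant, concatenated."""
        return pd.concat([f.frame for f in self.folds], ignore_index=True)

    def metrics_by_fold(self) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            cm = f.confusion
            rows.append(
                {
                    "participant_id": f.participant,
                    "selected_cp": f.selected_cp,
                    "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
                    "accuracy": cm.accuracy,
                    "sensitivity": cm.sensitivity,
                    "specificity": cm.specificity,
                    "ppv": cm.ppv,
                    "npv": cm.npv,
                    "f1": cm.f1,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        """Macro-averaged metrics with per-fold (min, max) ranges."""
        return _metrics.summarize_folds([f.confusion for f in self.folds])

    def pooled(self) -> "_metrics.ConfusionSummary":
        return _metrics.pooled_confusion([f.confusion for f in self.folds])
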