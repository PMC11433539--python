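"""Random-forest pathway prioritization via out-of-bag permutation importance.

A bagged ensemble of decision trees (sqrt-p features per split) classifies
the clinical phenotype from pathway expression.  Importance is the mean
decrease in out-of-bag accuracy, in percentage points, when one pathway's
column is permuted — the unit in which the selection threshold of 4 is
meaningful.  The bagging, OOB bookkeeping and permutation logic are
implemented here so the importance is genuinely out-of-bag; the individual
trees are scikit-learn decision trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)


@dataclass
class ForestModel:
    """Fitted bagged-tree ensemble with its bootstrap bookkeeping."""

    trees: list[DecisionTreeClassifier]
    oob_masks: np.ndarray  # (n_trees, n_samples) bool: sample OOB for tree
    classes: np.ndarray
    feature_names: list[str]
    oob_accuracy: float
    n_samples: int


def _encode_labels(y) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray([str(v) for v in y])
    classes = np.unique(y)
    codes = np.searchsorted(classes, y)
    return codes, classes


def train_forest(
    x: pd.DataFrame,
    y,
    n_trees: int = 500,
    seed: int = 0,
) -> ForestModel:
    """Fit a bagged decision-tree ensemble on samples × pathways features.

    Each tree is grown on a bootstrap sample with sqrt-p features considered
    per split and unlimited depth; out-of-bag accuracy is the accuracy of
    the majority OOB vote over samples with at least one OOB tree.
    Deterministic given ``seed``.
    """
    codes, classes = _encode_labels(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for ci, c in enumerate(classes):
        if (codes == ci).sum() < 3:
            raise ValueError(f"class {c!r} has fewer than 3 samples")
    values = x.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("features contain missing values")
    n, p = values.shape
    rng = np.random.default_rng(seed)
    trees: list[DecisionTreeClassifier] = []
    oob_masks = np.zeros((n_trees, n), dtype=bool)
    for t in range(n_trees):
        idx = rng.integers(0, n, size=n)
        mask = np.ones(n, dtype=bool)
        mask[idx] = False
        oob_masks[t] = mask
        tree = DecisionTreeClassifier(
            max_features="sqrt",
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(values[idx], codes[idx])
        trees.append(tree)
    model = ForestModel(
        trees=trees,
        oob_masks=oob_masks,
        classes=classes,
        feature_names=list(x.columns),
        oob_accuracy=0.0,
        n_samples=n,
    )
    model.oob_accuracy = _oob_accuracy(model, values, codes)
    return model


def _oob_votes(model: ForestModel, values: np.ndarray) -> np.ndarray:
    """Per-sample OOB class-vote counts, (n_samples, n_classes)."""
    n = values.shape[0]
    votes = np.zeros((n, len(model.classes)), dtype=np.int64)
    for tree, mask in zip(model.trees, model.oob_masks):
        if not mask.any():
            continue
        pred = tree.predict(values[mask])
        votes[np.where(mask)[0], pred.astype(int)] += 1
    return votes


def _oob_accuracy(model: ForestModel, values: np.ndarray, codes: np.ndarray) -> float:
    votes = _oob_votes(model, values)
    voted = votes.sum(axis=1) > 0
    if not voted.any():
        raise ValueError("no sample received an out-of-bag vote")
    pred = votes.argmax(axis=1)
    return float(np.mean(pred[voted] == codes[voted]))


def predict(model: ForestModel, x: pd.DataFrame) -> np.ndarray:
    """Majority-vote class labels for new samples."""
    values = x.loc[:, model.feature_names].to_numpy(dtype=float)
    votes = np.zeros((values.shape[0], len(model.classes)), dtype=np.int64)
    for tree in model.trees:
        pred = tree.predict(values)
        votes[np.arange(values.shape[0]), pred.astype(int)] += 1
    return model.classes[votes.argmax(axis=1)]


def permutation_importance(
    model: ForestModel,
    x: pd.DataFrame,
    y,
    n_repeats: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Out-of-bag permutation importance per pathway.

    For each feature the OOB accuracy is re-evaluated after permuting that
    column, ``n_repeats`` times with independent permutations;
    mean_decrease_accuracy = 100 × (baseline − mean permuted accuracy), in
    percentage points.  Returns an ImportanceTable DataFrame with columns
    ``mean_decrease_accuracy``, ``sd``, ``rank`` and ``selected`` (filled by
    :func:`select_signatures` semantics at the default threshold of 4).
    """
    codes, classes = _encode_labels(y)
    if list(classes) != list(model.classes):
        raise ValueError("labels do not match the fitted model's classes")
    values = x.loc[:, model.feature_names].to_numpy(dtype=float)
    n, p = values.shape
    if n != model.n_samples:
        raise ValueError("X does not match the training sample count")
    baseline = _oob_accuracy(model, values, codes)
    rng = np.random.default_rng(seed)
    n_classes = len(model.classes)
    oob_idx = [np.where(m)[0] for m in model.oob_masks]

    means = np.zeros(p)
    sds = np.zeros(p)
    for j in range(p):
        # stack all repeats into one block so each tree predicts once
        stacked = np.tile(values, (n_repeats, 1))
        for r in range(n_repeats):
            stacked[r * n : (r + 1) * n, j] = values[rng.permutation(n), j]
        votes = np.zeros((n_repeats, n, n_classes), dtype=np.int64)
        for tree, idx in zip(model.trees, oob_idx):
            if idx.size == 0:
                continue
            rows = (idx[None, :] + n * np.arange(n_repeats)[:, None]).ravel()
            pred = tree.predict(stacked[rows]).astype(int).reshape(n_repeats, -1)
            for r in range(n_repeats):
                votes[r, idx, pred[r]] += 1
        accs = np.empty(n_repeats)
        for r in range(n_repeats):
            voted = votes[r].sum(axis=1) > 0
            accs[r] = np.mean(votes[r].argmax(axis=1)[voted] == codes[voted])
        decrease = 100.0 * (baseline - accs)
        means[j] = decrease.mean()
        sds[j] = decrease.std(ddof=1) if n_repeats > 1 else 0.0

    table = pd.DataFrame(
        {
            "mean_decrease_accuracy": means,
            "sd": sds,
        },
        index=pd.Index(model.feature_names, name="pathway"),
    )
    order = table.sort_values(
        ["mean_decrease_accuracy"], ascending=False, kind="stable"
    ).index
    ranks = pd.Series(np.arange(1, p + 1), index=order)
    table["rank"] = ranks
    table["selected"] = table["mean_decrease_accuracy"] > 4.0
    return table


def select_signatures(
    importance: pd.DataFrame, threshold: float = 4.0
) -> list[str]:
    """Pathways whose mean decrease in accuracy strictly exceeds
    ``threshold``, ordered by decreasing importance (stable, ties broken by
    name)."""
    name = importance.index.name or "pathway"
    table = (
        importance.reset_index()
        .sort_values(by=name, kind="stable")
        .sort_values(by="mean_decrease_accuracy", ascending=False, kind="stable")
        .set_index(name)
    )
    chosen = table.index[table["mean_decrease_accuracy"] > threshold]
    if len(chosen) == 0:
        logger.warning("no pathway exceeded importance threshold %s", threshold)
    return list(chosen)
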