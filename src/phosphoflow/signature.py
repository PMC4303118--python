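"""Two-step random-forest site signature.

Step 1 trains a forest on all (reproducible) sites and computes per-class
permutation importances on out-of-bag samples: for every tree, each used
feature is permuted among the tree's OOB rows and the drop in class-wise
OOB accuracy is recorded; importances are the per-tree drops averaged over
all trees, expressed in percentage points.  Step 2 retrains on the sites
whose importance exceeds the threshold for at least one class.

Samples are canonically ordered before fitting so results are invariant to
input sample order; everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .preprocess import IntensityMatrix
from .tables_io import write_json

logger = logging.getLogger(__name__)


class SignatureError(ValueError):
    pass


@dataclass
class SignatureModel:
    """Result of the two-step selection plus the fitted step-2 forest."""

    step1_oob_error: float
    step2_oob_error: float
    importances: pd.DataFrame  # sites x classes, percentage points
    importances_scaled: pd.DataFrame  # z-scored variant (per class)
    selected_sites: list[str]
    threshold: float
    seed: int
    n_trees: int
    classes: list[str]
    forest: RandomForestClassifier = field(repr=False, default=None)

    def to_json_dict(self) -> dict:
        return {
            "step1_oob_error": self.step1_oob_error,
            "step2_oob_error": self.step2_oob_error,
            "selected_sites": self.selected_sites,
            "threshold": self.threshold,
            "seed": self.seed,
            "n_trees": self.n_trees,
            "classes": self.classes,
            "importances": {
                s: {c: float(self.importances.loc[s, c]) for c in self.importances.columns}
                for s in self.importances.index
            },
        }

    def save(self, path) -> None:
        write_json(self.to_json_dict(), path)


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _bootstrap_indices(tree_random_state: int, n_samples: int) -> np.ndarray:
    """Reproduce the bootstrap sample drawn for one tree.

    scikit-learn draws bootstrap rows for each estimator as
    RandomState(tree.random_state).randint(0, n, n); the OOB rows are the
    complement.  Verified against the forest's own OOB votes in the test
    suite so a library change cannot silently break this.
    """
    rs = np.random.RandomState(tree_random_state)
    return rs.randint(0, n_samples, n_samples)


def _per_class_permutation_importance(
    clf: RandomForestClassifier,
    X: np.ndarray,
    y_codes: np.ndarray,
    n_classes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """features x classes matrix of mean decrease in class-wise OOB accuracy,
    in percentage points.  Features a tree never splits on contribute 0 for
    that tree."""
    n_samples, n_features = X.shape
    total = np.zeros((n_features, n_classes))
    for tree in clf.estimators_:
        sampled = _bootstrap_indices(tree.random_state, n_samples)
        oob = np.setdiff1d(np.arange(n_samples), sampled)
        if len(oob) == 0:
            continue
        X_oob = X[oob]
        y_oob = y_codes[oob]
        base_pred = tree.predict(X_oob).astype(int)
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        class_counts = np.bincount(y_oob, minlength=n_classes).astype(float)
        base_correct = np.zeros(n_classes)
        np.add.at(base_correct, y_oob[base_pred == y_oob], 1.0)
        for j in used:
            perm = rng.permutation(len(oob))
            X_perm = X_oob.copy()
            X_perm[:, j] = X_oob[perm, j]
            pred = tree.predict(X_perm).astype(int)
            perm_correct = np.zeros(n_classes)
            np.add.at(perm_correct, y_oob[pred == y_oob], 1.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                drop = np.where(
                    class_counts > 0,
                    (base_correct - perm_correct) / class_counts,
                    0.0,
                )
            total[j] += drop
    return total / clf.n_estimators * 100.0


def _oob_error(clf: RandomForestClassifier, y_codes: np.ndarray) -> float:
    votes = clf.oob_decision_function_
    pred = np.argmax(votes, axis=1)
    valid = ~np.isnan(votes).any(axis=1)
    return float(np.mean(pred[valid] != y_codes[valid]))


def _fit_forest(
    X: np.ndarray, y: np.ndarray, n_trees: int, seed: int
) -> RandomForestClassifier:
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    return clf


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def train_two_step(
    matrix: IntensityMatrix,
    threshold: float = 1.2,
    n_trees: int = 2000,
    seed: int = 0,
    importance_scale: str = "raw",
) -> SignatureModel:
    """Train the two-step forest and return the distilled signature.

    Selection keeps sites whose per-class importance is strictly above
    ``threshold`` for at least one class; ``importance_scale`` chooses the
    raw percentage-point importances (default) or their per-class z-scores.
    """
    if importance_scale not in ("raw", "scaled"):
        raise SignatureError(f"unknown importance_scale: {importance_scale!r}")
    samples = sorted(matrix.samples)
    classes = sorted(set(matrix.class_of[s] for s in samples))
    if len(classes) < 2:
        raise SignatureError("need >= 2 classes")
    for c in classes:
        if sum(matrix.class_of[s] == c for s in samples) < 2:
            raise SignatureError(f"class {c!r} has < 2 samples")
    if not matrix.is_complete():
        raise SignatureError("matrix must be complete (imputed)")

    sites = list(matrix.sites)
    X = matrix.values[samples].to_numpy(dtype=float).T  # samples x sites
    y = np.array([matrix.class_of[s] for s in samples])
    y_codes = np.searchsorted(np.array(classes), y)

    clf1 = _fit_forest(X, y_codes, n_trees, seed)
    step1_err = _oob_error(clf1, y_codes)
    rng = np.random.default_rng(seed + 1)
    raw = _per_class_permutation_importance(clf1, X, y_codes, len(classes), rng)
    importances = pd.DataFrame(raw, index=sites, columns=classes)
    sd = importances.std(axis=0).replace(0.0, 1.0)
    scaled = (importances - importances.mean(axis=0)) / sd

    basis = importances if importance_scale == "raw" else scaled
    selected = [s for s in sites if (basis.loc[s] > threshold).any()]
    if not selected:
        raise SignatureError(
            f"no site has importance > {threshold}; lower the threshold"
        )

    sel_idx = [sites.index(s) for s in selected]
    clf2 = _fit_forest(X[:, sel_idx], y_codes, n_trees, seed)
    step2_err = _oob_error(clf2, y_codes)
    logger.info(
        "train_two_step: %d -> %d sites, OOB %.4f -> %.4f",
        len(sites), len(selected), step1_err, step2_err,
    )
    return SignatureModel(
        step1_oob_error=step1_err,
        step2_oob_error=step2_err,
        importances=importances,
        importances_scaled=scaled,
        selected_sites=selected,
        threshold=threshold,
        seed=seed,
        n_trees=n_trees,
        classes=classes,
        forest=clf2,
    )


def predict(model: SignatureModel, matrix: IntensityMatrix) -> pd.DataFrame:
    """Classify samples with the step-2 forest.

    Returns a frame indexed by sample with a ``label`` column and one vote
    fraction column per class (rows sum to 1).
    """
    absent = [s for s in model.selected_sites if s not in set(matrix.sites)]
    if absent:
        raise SignatureError(f"input matrix lacks selected site(s): {absent}")
    X = matrix.values.loc[model.selected_sites].to_numpy(dtype=float).T
    votes = model.forest.predict_proba(X)
    labels = [model.classes[i] for i in np.argmax(votes, axis=1)]
    out = pd.DataFrame(votes, index=matrix.samples, columns=model.classes)
    out.insert(0, "label", labels)
    return out
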