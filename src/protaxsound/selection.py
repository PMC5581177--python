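"""Random-forest importance pre-selection of cross-correlation features.

A large reference-template bank makes classification slow and can dilute
accuracy with redundant or noisy templates.  The selector ranks templates by
forest importance, retrains on shrinking top-ranked prefixes, and keeps the
smallest prefix whose internal accuracy is within a tolerance of the best —
"highest accuracy from as few features as possible".  Internal accuracy is
measured on the training data only (out-of-bag or internal CV), never on a
held-out test fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import cross_val_score

from .classifiers import XCorrRandomForest

__all__ = ["rank_features", "select_subset", "SelectionResult"]


def rank_features(model: XCorrRandomForest) -> np.ndarray:
    """Feature ids sorted by forest importance, descending; ties broken by
    ascending feature id."""
    imp = getattr(model, "feature_importances_", None)
    if imp is None:
        raise TypeError("feature ranking requires a fitted random-forest model")
    ids = np.arange(len(imp))
    return ids[np.lexsort((ids, -np.asarray(imp)))]


@dataclass
class SelectionResult:
    chosen: np.ndarray          # selected feature ids (a prefix of the ranking)
    ranking: np.ndarray
    curve: pd.DataFrame         # fraction, n_features, accuracy


def select_subset(
    X: np.ndarray,
    y: np.ndarray,
    fractions=(1.0, 0.8, 0.6, 0.4, 0.2, 0.1),
    seed: int = 0,
    tolerance: float = 0.005,
    n_estimators: int = 200,
    cv: int = 3,
) -> SelectionResult:
    """Pick the smallest top-importance feature prefix with near-best accuracy.

    For each fraction in the (decreasing) schedule the forest is retrained on
    the top-ranked subset and scored by ``cv``-fold accuracy on the training
    data; the smallest subset within ``tolerance`` of the curve maximum wins.
    """
    fracs = list(fractions)
    if any(not (0 < f <= 1) for f in fracs):
        raise ValueError("fractions must lie in (0, 1]")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    base = XCorrRandomForest(n_estimators=n_estimators, random_state=seed).fit(X, y)
    ranking = rank_features(base)
    rows = []
    for frac in fracs:
        k = max(1, int(round(frac * X.shape[1])))
        subset = ranking[:k]
        model = XCorrRandomForest(n_estimators=n_estimators, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            acc = float(
                np.mean(cross_val_score(model, X[:, subset], y, cv=cv, scoring="accuracy"))
            )
        rows.append({"fraction": frac, "n_features": k, "accuracy": acc})
    curve = pd.DataFrame(rows)
    best = curve["accuracy"].max()
    ok = curve[curve["accuracy"] >= best - tolerance]
    k_star = int(ok["n_features"].min())
    return SelectionResult(chosen=ranking[:k_star], ranking=ranking, curve=curve)
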