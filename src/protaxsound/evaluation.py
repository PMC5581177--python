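"""Accuracy and calibration diagnostics, plus leakage-safe CV folds.

Calibration is judged the way a practitioner reads a reliability diagram:
sort the per-query top probabilities ascending, pair each with whether the
top outcome was correct, and plot cumulative predicted probability against
cumulative correct count.  A calibrated classifier tracks the identity line;
our scalar summary is the mean absolute cumulative gap divided by n.

Species-level calibration gets an empirical two-tailed p-value against a
Bernoulli null: simulate the number of correct outcomes for a species by
summing Bernoulli draws at the predicted top probabilities of its samples.

Cross-validation folds treat (author, day, species) groups as atomic so
recordings that may capture the same individual never straddle the
training/test split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protax import UNKNOWN, ClassificationResult

__all__ = [
    "top1_accuracy",
    "ReliabilityCurve",
    "reliability_curve",
    "SpeciesCalibration",
    "species_calibration_pvalues",
    "plot_reliability",
    "make_cv_folds",
]


def _tops(results: list[ClassificationResult]) -> tuple[np.ndarray, np.ndarray]:
    """Top outcome and its probability per query; ties broken by outcome
    order (species id ascending, unknown last)."""
    labels, probs = [], []
    for r in results:
        order = np.argsort(r.outcomes[:-1])  # species sorted by id
        ordered = [r.outcomes[i] for i in order] + [UNKNOWN]
        p = np.concatenate([r.probabilities[order], [r.probabilities[-1]]])
        i = int(np.argmax(p))  # first max wins -> species-id tie rule
        labels.append(ordered[i])
        probs.append(float(p[i]))
    return np.asarray(labels), np.asarray(probs)


def _correct(top_labels: np.ndarray, truth: list[str], in_database: list[bool] | None) -> np.ndarray:
    """A query is correct when the top outcome equals its true species;
    'unknown' is correct only for queries whose species is absent from the
    reference database."""
    if in_database is None:
        in_database = [t != UNKNOWN for t in truth]
    out = np.zeros(len(truth), dtype=bool)
    for i, (lab, t, indb) in enumerate(zip(top_labels, truth, in_database)):
        out[i] = (lab == t) if indb else (lab == UNKNOWN)
    return out


def top1_accuracy(
    results: list[ClassificationResult],
    truth: list[str],
    in_database: list[bool] | None = None,
) -> float:
    """Fraction of queries whose highest-probability outcome is correct."""
    if len(results) != len(truth):
        raise ValueError("every result needs a truth label")
    labels, _ = _tops(results)
    return float(_correct(labels, truth, in_database).mean())


@dataclass
class ReliabilityCurve:
    """Cumulative predicted vs observed correctness, probabilities ascending."""

    p_sorted: np.ndarray
    cum_predicted: np.ndarray   # C_i = sum_{j<=i} p_(j)
    cum_correct: np.ndarray     # K_i = sum_{j<=i} y_(j)
    deviation: float            # mean |K_i - C_i| / n

    @property
    def n(self) -> int:
        return self.p_sorted.size

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"i": np.arange(1, self.n + 1), "p": self.p_sorted,
             "cum_predicted": self.cum_predicted, "cum_correct": self.cum_correct}
        )


def reliability_curve(top_probs: np.ndarray, correct: np.ndarray) -> ReliabilityCurve:
    """Reliability diagram data from per-query top probabilities and hits."""
    p = np.asarray(top_probs, dtype=np.float64)
    y = np.asarray(correct, dtype=np.float64)
    if p.size != y.size or p.size < 1:
        raise ValueError("need matching, non-empty probability/correctness arrays")
    order = np.argsort(p, kind="stable")
    ps = p[order]
    C = np.cumsum(ps)
    K = np.cumsum(y[order])
    dev = float(np.mean(np.abs(K - C)) / p.size)
    return ReliabilityCurve(ps, C, K, dev)


def reliability_from_results(
    results: list[ClassificationResult],
    truth: list[str],
    in_database: list[bool] | None = None,
) -> ReliabilityCurve:
    labels, probs = _tops(results)
    return reliability_curve(probs, _correct(labels, truth, in_database))


@dataclass
class SpeciesCalibration:
    species: str
    n: int
    k: int                      # observed correct count
    p_value: float
    null_mean: float


def species_calibration_pvalues(
    results: list[ClassificationResult],
    truth: list[str],
    n_sims: int = 10000,
    seed: int = 0,
    method: str = "double",
) -> list[SpeciesCalibration]:
    """Per-species two-tailed calibration p-values against a Bernoulli null.

    For each species with n test samples, the null distribution of the
    correct count is n Bernoulli trials at the predicted top probabilities,
    simulated ``n_sims`` times.  ``method="double"`` doubles the smaller
    empirical tail (capped at 1); ``method="point"`` accumulates outcomes as
    or more extreme than observed.
    """
    if n_sims < 1000:
        warnings.warn("n_sims < 1000 gives unstable tail estimates", stacklevel=2)
    labels, probs = _tops(results)
    hits = _correct(labels, truth, None)
    rng = np.random.default_rng(seed)
    out = []
    for sp in sorted(set(truth)):
        idx = np.asarray([i for i, t in enumerate(truth) if t == sp])
        p = probs[idx]
        k = int(hits[idx].sum())
        sims = (rng.random((n_sims, p.size)) < p).sum(axis=1)
        lo = float(np.mean(sims <= k))
        hi = float(np.mean(sims >= k))
        if method == "double":
            pval = min(1.0, 2 * min(lo, hi))
        elif method == "point":
            # sum the null mass of all outcomes no more likely than observed
            vals, counts = np.unique(sims, return_counts=True)
            pmf = counts / n_sims
            pk = float(pmf[vals == k][0]) if np.any(vals == k) else 0.0
            pval = float(pmf[pmf <= pk + 1e-12].sum())
        else:
            raise ValueError(f"unknown method {method!r}")
        pval = max(pval, 1.0 / n_sims)
        out.append(SpeciesCalibration(sp, p.size, k, pval, float(sims.mean())))
    return out


def plot_reliability(curves: dict[str, ReliabilityCurve], path: str) -> None:
    """Write a reliability diagram (cumulative predicted vs observed) for one
    or more named curves, with the identity line for reference."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    top = 1.0
    for name, c in curves.items():
        ax.plot(c.cum_predicted, c.cum_correct, label=f"{name} (dev {c.deviation:.3f})")
        top = max(top, c.cum_predicted[-1], c.cum_correct[-1])
    ax.plot([0, top], [0, top], color="grey", lw=1, ls="--", label="identity")
    ax.set_xlabel("cumulative predicted top probability")
    ax.set_ylabel("cumulative correct classifications")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def make_cv_folds(metadata: pd.DataFrame, k: int = 5, seed: int = 0) -> np.ndarray:
    """Grouped k-fold assignment, one fold id per metadata row.

    Rows sharing (author, day, species) form atomic groups.  Each species'
    groups are dealt round-robin across folds (starting at the currently
    smallest fold) so species spread as evenly as the group structure
    allows.  Deterministic given the seed.
    """
    required = {"species_id", "author", "day"}
    if not required.issubset(metadata.columns):
        raise ValueError(f"metadata needs columns {sorted(required)}")
    rng = np.random.default_rng(seed)
    fold_of = np.full(len(metadata), -1, dtype=int)
    fold_sizes = np.zeros(k, dtype=int)
    keys = metadata[["author", "day", "species_id"]].astype(str).agg("|".join, axis=1)
    for sp in sorted(metadata["species_id"].astype(str).unique()):
        sp_mask = metadata["species_id"].astype(str) == sp
        groups = sorted(keys[sp_mask].unique())
        if len(groups) < k and k > 1:
            warnings.warn(
                f"species {sp} has only {len(groups)} atomic group(s); it cannot "
                f"appear in every fold", stacklevel=2,
            )
        order = rng.permutation(len(groups))
        start = int(np.argmin(fold_sizes))
        for j, gi in enumerate(order):
            fold = (start + j) % k
            rows = np.flatnonzero(sp_mask.to_numpy() & (keys == groups[gi]).to_numpy())
            fold_of[rows] = fold
            fold_sizes[fold] += rows.size
    assert np.all(fold_of >= 0)
    return fold_of
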