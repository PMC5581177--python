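"""Calibrated multinomial classification over species plus "unknown".

The statistical heart of the package.  For a query sample and each candidate
species the model sees eight predictors:

* x1..x6 — the minimum blockwise MFCC-summary dissimilarities between the
  query and the candidate species' reference samples (per mean/variance x
  MFCC/Delta/Delta-Delta block);
* x7, x8 — modified-logit transforms of the class probability the random
  forest / convolutional network assigns to the candidate species, with
  logit(eps + (1 - 2 eps) p) and eps = 0.001 so p = 0 and p = 1 stay finite.

Membership probabilities follow a flat multinomial logistic decomposition:
P(species s) ~ exp(beta_0 + sum_k beta_k x_sk) with a shared intercept and
shared slopes, and the open-set "unknown species" outcome as the reference
category with linear predictor 0.  This is Platt scaling generalized to many
classes plus an explicit unknown class.

Training data are leave-one-out pseudo-queries built from the reference
database itself: each reference sample yields one event where its species
must be recovered without it (known mode) and one where its whole species is
removed and "unknown" is the correct answer (unknown mode).  Coefficients
are estimated by penalized maximum likelihood (Gaussian prior) with L-BFGS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .features import BLOCK_NAMES, block_distances

__all__ = [
    "modified_logit",
    "ReferenceDatabase",
    "TrainingEvent",
    "build_predictors",
    "generate_training_events",
    "ProtaxCalibrator",
    "ClassificationResult",
    "simulate_events",
    "UNKNOWN",
]

UNKNOWN = "unknown"


def modified_logit(p, eps: float = 0.001):
    """logit(eps + (1 - 2 eps) p): finite for p in [0, 1] inclusive.

    Strictly increasing in p and antisymmetric about p = 0.5; at the
    default eps it maps 0 -> -6.9068, 0.5 -> 0, 1 -> +6.9068.
    """
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if not (0 < eps < 0.5):
        raise ValueError("eps must lie in (0, 0.5)")
    q = eps + (1 - 2 * eps) * p
    out = np.log(q / (1 - q))
    return float(out) if out.ndim == 0 else out


@dataclass
class ReferenceDatabase:
    """Labeled reference samples: one 96-dim MFCC summary per sample.

    ``species`` fixes the candidate/class order used everywhere downstream;
    base-classifier probability vectors must be aligned to it.
    """

    sample_ids: list[str]
    species_of: np.ndarray          # species label per sample
    summaries: np.ndarray           # (n_samples, 96)
    species: list[str] = field(default_factory=list)
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.species_of = np.asarray(self.species_of)
        self.summaries = np.asarray(self.summaries, dtype=np.float64)
        if not self.species:
            self.species = sorted(set(self.species_of.tolist()))
        if len(self.sample_ids) != self.summaries.shape[0]:
            raise ValueError("sample_ids and summaries disagree in length")
        if self.summaries.ndim != 2:
            raise ValueError("summaries must be (n_samples, n_features)")

    @property
    def n_samples(self) -> int:
        return self.summaries.shape[0]

    def block_distance_matrices(self) -> np.ndarray:
        """(6, n, n) pairwise blockwise distances between all summaries."""
        n = self.n_samples
        width = self.summaries.shape[1] // 6
        blocks = self.summaries.reshape(n, 6, width)
        out = np.empty((6, n, n))
        for b in range(6):
            x = blocks[:, b, :]
            sq = (x**2).sum(axis=1)
            d2 = sq[:, None] + sq[None, :] - 2 * (x @ x.T)
            out[b] = np.sqrt(np.maximum(d2, 0.0))
        return out


def _species_minima(
    dists: np.ndarray,            # (6, n_refs) distances query -> each reference
    species_of: np.ndarray,
    species: list[str],
    exclude: np.ndarray | None = None,
    sentinel: np.ndarray | None = None,
) -> np.ndarray:
    """Per-species blockwise minima, (n_species, 6).

    Species left without reference samples (after exclusions) receive the
    ``sentinel`` distances — "no evidence of similarity" on the distance
    scale.
    """
    if sentinel is None:
        sentinel = dists.max(axis=1)
    keep = np.ones(dists.shape[1], dtype=bool) if exclude is None else ~exclude
    out = np.empty((len(species), 6))
    for i, sp in enumerate(species):
        sel = keep & (species_of == sp)
        out[i] = dists[:, sel].min(axis=1) if sel.any() else sentinel
    return out


def build_predictors(
    query_summary: np.ndarray,
    refdb: ReferenceDatabase,
    rf_probs: np.ndarray,
    cn_probs: np.ndarray,
    eps: float = 0.001,
    exclude_sample: int | None = None,
    sentinel: np.ndarray | None = None,
) -> np.ndarray:
    """The (n_species, 8) predictor matrix for one query.

    ``rf_probs``/``cn_probs`` must be aligned to ``refdb.species``.
    ``exclude_sample`` removes one reference sample (leave-one-out) before
    taking the per-species distance minima.
    """
    for name, p in (("rf", rf_probs), ("cn", cn_probs)):
        if len(p) != len(refdb.species):
            raise ValueError(
                f"{name} probabilities have {len(p)} classes but the reference "
                f"database lists species {refdb.species}"
            )
    dists = np.stack(
        [block_distances(query_summary, s) for s in refdb.summaries], axis=1
    )  # (6, n_refs)
    exclude = None
    if exclude_sample is not None:
        exclude = np.zeros(refdb.n_samples, dtype=bool)
        exclude[exclude_sample] = True
    x16 = _species_minima(dists, refdb.species_of, refdb.species, exclude, sentinel)
    x7 = modified_logit(np.asarray(rf_probs, dtype=np.float64), eps)
    x8 = modified_logit(np.asarray(cn_probs, dtype=np.float64), eps)
    return np.column_stack([x16, x7, x8])


@dataclass
class TrainingEvent:
    """One leave-one-out pseudo-query with its candidate set and truth."""

    X: np.ndarray                  # (n_candidates, 8) predictors
    candidates: list[str]          # candidate species (unknown is implicit)
    truth: str                     # a species label or UNKNOWN
    query_id: str = ""
    mode: str = "known"            # "known" | "unknown"

    def __post_init__(self) -> None:
        if self.truth != UNKNOWN and self.truth not in self.candidates:
            raise ValueError(f"truth {self.truth!r} not among candidates")


def generate_training_events(
    refdb: ReferenceDatabase,
    rf_probs: np.ndarray,
    cn_probs: np.ndarray,
    eps: float = 0.001,
    dist_matrices: np.ndarray | None = None,
    renormalize_unknown: bool = False,
) -> list[TrainingEvent]:
    """Two events per reference sample: known-species and unknown mimicry.

    ``rf_probs``/``cn_probs`` are (n_samples, n_species) out-of-fold
    probabilities for every reference sample treated as a query (the
    providers must not have seen the sample itself in training).  Known
    mode removes the query from its own species' references; unknown mode
    removes the query's species (and its references) from the candidate set.
    The per-block sentinel for reference-less species is the maximum distance
    observed in the database.
    """
    if refdb.n_samples == 0:
        raise ValueError("empty reference database")
    dm = refdb.block_distance_matrices() if dist_matrices is None else dist_matrices
    sentinel = dm.reshape(6, -1).max(axis=1)
    species = refdb.species
    events: list[TrainingEvent] = []
    for q in range(refdb.n_samples):
        dists = dm[:, q, :]
        exclude = np.zeros(refdb.n_samples, dtype=bool)
        exclude[q] = True
        x16 = _species_minima(dists, refdb.species_of, species, exclude, sentinel)
        x7 = modified_logit(np.asarray(rf_probs[q], dtype=np.float64), eps)
        x8 = modified_logit(np.asarray(cn_probs[q], dtype=np.float64), eps)
        X = np.column_stack([x16, x7, x8])
        q_sp = refdb.species_of[q]
        qid = refdb.sample_ids[q]
        events.append(TrainingEvent(X=X, candidates=list(species), truth=q_sp,
                                    query_id=qid, mode="known"))
        keep = [i for i, sp in enumerate(species) if sp != q_sp]
        Xu = X[keep].copy()
        if renormalize_unknown:
            # optional: spread the removed species' probability mass over the
            # remaining classes, as a classifier trained without it would
            for col, probs in ((6, rf_probs), (7, cn_probs)):
                p_keep = np.asarray(probs[q], dtype=np.float64)[keep]
                total = p_keep.sum()
                if total > 0:
                    Xu[:, col] = modified_logit(np.clip(p_keep / total, 0.0, 1.0), eps)
        events.append(
            TrainingEvent(X=Xu, candidates=[species[i] for i in keep],
                          truth=UNKNOWN, query_id=qid, mode="unknown")
        )
    return events


@dataclass
class ClassificationResult:
    """Membership probabilities over species plus "unknown" for one query."""

    query_id: str
    outcomes: list[str]            # species..., UNKNOWN last
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=np.float64)
        if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must form a distribution (sum 1)")
        self.probabilities = p

    def ranked(self) -> pd.DataFrame:
        order = np.argsort(-self.probabilities, kind="stable")
        return pd.DataFrame(
            {
                "query_id": self.query_id,
                "outcome": [self.outcomes[i] for i in order],
                "probability": self.probabilities[order],
                "rank": np.arange(1, len(order) + 1),
            }
        )

    @property
    def top(self) -> tuple[str, float]:
        i = int(np.argmax(self.probabilities))
        return self.outcomes[i], float(self.probabilities[i])


class ProtaxCalibrator(BaseEstimator):
    """Penalized multinomial logistic calibration with an unknown outcome.

    Parameters
    ----------
    prior_sd : Gaussian prior standard deviation on the intercept and slopes
        (penalized maximum likelihood; larger = weaker shrinkage).
    eps : modified-logit floor for the probability predictors.
    predictor_mask : optional boolean mask (length 8) restricting the model
        to a predictor subset (e.g. MFCC-only, RF-only, CN-only variants);
        masked-out slopes are fixed at zero.

    Fitted attributes: ``intercept_``, ``coef_`` (length 8, zeros where
    masked), ``x_mean_``/``x_sd_`` standardization constants, ``converged_``,
    ``loglik_``.
    """

    def __init__(self, prior_sd: float = 10.0, eps: float = 0.001,
                 predictor_mask=None, seed: int = 0):
        self.prior_sd = prior_sd
        self.eps = eps
        self.predictor_mask = predictor_mask
        self.seed = seed

    # -- internal: stack events into one design -------------------------------
    def _stack(self, events: list[TrainingEvent]):
        """Rows = candidate outcomes (incl. one all-zero unknown row per
        event); returns (Xaug, event row offsets, truth row index)."""
        rows, offsets, truth_rows = [], [0], []
        for e in events:
            Xs = (e.X - self.x_mean_) / self.x_sd_
            Xs = Xs * self._mask
            aug = np.column_stack([np.ones(len(e.candidates)), Xs])
            aug = np.vstack([aug, np.zeros(aug.shape[1])])  # unknown row
            if e.truth == UNKNOWN:
                truth_rows.append(offsets[-1] + aug.shape[0] - 1)
            else:
                truth_rows.append(offsets[-1] + e.candidates.index(e.truth))
            rows.append(aug)
            offsets.append(offsets[-1] + aug.shape[0])
        return np.vstack(rows), np.asarray(offsets[:-1]), np.asarray(truth_rows)

    def fit(self, events: list[TrainingEvent]):
        if not events:
            raise ValueError("no training events")
        modes = {e.mode for e in events}
        if modes == {"known"} or modes == {"unknown"}:
            raise ValueError("need both known- and unknown-mode events to fit")
        n_pred = events[0].X.shape[1]
        mask = (np.ones(n_pred, dtype=bool) if self.predictor_mask is None
                else np.asarray(self.predictor_mask, dtype=bool))
        if mask.size != n_pred:
            raise ValueError(f"predictor_mask must have length {n_pred}")
        self._mask = mask
        self.n_predictors_ = n_pred
        allX = np.vstack([e.X for e in events])
        self.x_mean_ = allX.mean(axis=0)
        sd = allX.std(axis=0)
        self.x_sd_ = np.where(sd > 1e-12, sd, 1.0)
        Xaug, offsets, truth_rows = self._stack(events)
        n_events = len(events)
        lam = 1.0 / (2.0 * self.prior_sd**2)

        def negloglik(theta):
            scores = Xaug @ theta
            # per-event log-sum-exp over contiguous row blocks
            maxs = np.maximum.reduceat(scores, offsets)
            lens = np.diff(np.append(offsets, scores.size))
            shifted = np.exp(scores - np.repeat(maxs, lens))
            sums = np.add.reduceat(shifted, offsets)
            lse = maxs + np.log(sums)
            ll = scores[truth_rows].sum() - lse.sum()
            # softmax responsibilities for the gradient
            p = shifted / np.repeat(sums, lens)
            np.subtract.at(p, truth_rows, 1.0)
            grad = Xaug.T @ p
            return -(ll - lam * theta @ theta), grad + 2 * lam * theta

        theta0 = np.zeros(1 + n_pred)
        res = minimize(negloglik, theta0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 500})
        self.converged_ = bool(res.success)
        self.intercept_ = float(res.x[0])
        self.coef_ = res.x[1:] * mask
        self._theta = np.concatenate([[self.intercept_], self.coef_])
        self.loglik_ = float(-res.fun)  # penalized log-likelihood at optimum
        self.n_events_ = n_events
        return self

    def standard_errors(self, events: list[TrainingEvent], h: float = 1e-5) -> np.ndarray:
        """Asymptotic standard errors from the numerical Hessian of the
        penalized negative log-likelihood at the estimate."""
        Xaug, offsets, truth_rows = self._stack(events)
        lam = 1.0 / (2.0 * self.prior_sd**2)

        def grad_only(theta):
            scores = Xaug @ theta
            maxs = np.maximum.reduceat(scores, offsets)
            lens = np.diff(np.append(offsets, scores.size))
            shifted = np.exp(scores - np.repeat(maxs, lens))
            sums = np.add.reduceat(shifted, offsets)
            p = shifted / np.repeat(sums, lens)
            np.subtract.at(p, truth_rows, 1.0)
            return Xaug.T @ p + 2 * lam * theta

        k = self._theta.size
        H = np.zeros((k, k))
        for i in range(k):
            step = np.zeros(k)
            step[i] = h
            H[:, i] = (grad_only(self._theta + step) - grad_only(self._theta - step)) / (2 * h)
        H = (H + H.T) / 2
        return np.sqrt(np.diag(np.linalg.inv(H)))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probabilities over candidates + unknown (last) for one query.

        ``X`` is the (n_candidates, 8) predictor matrix on the original
        scale; standardization constants from training are applied here.
        """
        Xs = (np.asarray(X, dtype=np.float64) - self.x_mean_) / self.x_sd_
        Xs = Xs * self._mask
        scores = self.intercept_ + Xs @ self.coef_
        scores = np.append(scores, 0.0)  # unknown outcome
        scores -= scores.max()
        p = np.exp(scores)
        p /= p.sum()
        return p

    def classify(self, query_id: str, X: np.ndarray, candidates: list[str]) -> ClassificationResult:
        if len(candidates) != np.asarray(X).shape[0]:
            raise ValueError("one predictor row per candidate species required")
        p = self.predict_proba(X)
        return ClassificationResult(query_id, list(candidates) + [UNKNOWN], p)

    # -- persistence ----------------------------------------------------------
    def to_json(self, species: list[str]) -> str:
        return json.dumps(
            {
                "version": 1,
                "eps": self.eps,
                "prior_sd": self.prior_sd,
                "intercept": self.intercept_,
                "coef": self.coef_.tolist(),
                "x_mean": self.x_mean_.tolist(),
                "x_sd": self.x_sd_.tolist(),
                "mask": self._mask.tolist(),
                "converged": self.converged_,
                "loglik": self.loglik_,
                "species": species,
                "predictor_names": [f"x{i}" for i in range(1, 7)] + ["x7_rf", "x8_cn"],
                "block_names": list(BLOCK_NAMES),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> tuple["ProtaxCalibrator", list[str]]:
        d = json.loads(text)
        cal = cls(prior_sd=d["prior_sd"], eps=d["eps"])
        cal.intercept_ = d["intercept"]
        cal.coef_ = np.asarray(d["coef"])
        cal.x_mean_ = np.asarray(d["x_mean"])
        cal.x_sd_ = np.asarray(d["x_sd"])
        cal._mask = np.asarray(d["mask"], dtype=bool)
        cal.converged_ = d["converged"]
        cal.loglik_ = d["loglik"]
        cal._theta = np.concatenate([[cal.intercept_], cal.coef_])
        return cal, d["species"]


def simulate_events(
    beta0: float,
    beta: np.ndarray,
    n_events: int,
    n_candidates: int = 10,
    seed: int = 0,
    unknown_fraction: float = 0.5,
) -> list[TrainingEvent]:
    """Draw synthetic training events from known coefficients.

    Predictors are standard normal (i.e. already on the standardized scale),
    outcomes are sampled from the model's own softmax over candidates plus
    the unknown reference outcome.  Used for parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=np.float64)
    species = [f"s{i}" for i in range(n_candidates)]
    events = []
    for k in range(n_events):
        m = n_candidates if rng.random() > unknown_fraction else n_candidates - 1
        X = rng.standard_normal((m, beta.size))
        scores = np.append(beta0 + X @ beta, 0.0)
        scores -= scores.max()
        p = np.exp(scores)
        p /= p.sum()
        y = rng.choice(m + 1, p=p)
        truth = UNKNOWN if y == m else species[y]
        mode = "unknown" if truth == UNKNOWN else "known"
        events.append(TrainingEvent(X=X, candidates=species[:m], truth=truth,
                                    query_id=f"sim{k}", mode=mode))
    return events
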