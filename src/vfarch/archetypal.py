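"""Archetypal analysis: fitting, decomposition, cross-validation, model order.

Each observation (a 52-location binocular field) is represented as a convex
combination of K archetypes, themselves convex combinations of the
observations (Cutler-Breiman).  Fitting alternates simplex-constrained
least-squares steps; the simplex projections go through non-negative least
squares on a sum-constraint-augmented system (penalty row M) with exact
renormalization and a KKT polish of the detected support.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import _solvers
from .core import BINOC_MAX_DB, SHARED_NAMES, IntegratedVF

log = logging.getLogger(__name__)

DEFAULT_PENALTY = 200.0
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 100
DEFAULT_RESTARTS = 100

_MODEL_SCHEMA_VERSION = 1

#: CV score convention: mean, over validation fields, of the squared
#: reconstruction residual of each field (fold-size robust).
CV_NORMALIZATION = "mean_squared_residual_per_field"


def simplex_ls(
    target: np.ndarray, basis: np.ndarray, penalty: float = DEFAULT_PENALTY
) -> tuple[np.ndarray, float]:
    """Project ``target`` onto the convex hull of the rows of ``basis``.

    Returns ``(weights, residual)`` where weights lie on the m-simplex and
    residual is the squared Euclidean reconstruction error.  Solved by NNLS
    on the system augmented with a constant row of magnitude ``penalty``,
    exact renormalization, and a KKT active-set polish of the support.
    """
    basis = np.atleast_2d(np.asarray(basis, dtype=float))
    target = np.asarray(target, dtype=float).ravel()
    if basis.shape[0] == 0:
        raise ValueError("simplex_ls requires at least one basis row")
    if basis.shape[1] != target.size:
        raise ValueError(
            f"dimension mismatch: target {target.size}, basis {basis.shape[1]}"
        )
    if not (np.all(np.isfinite(basis)) and np.all(np.isfinite(target))):
        raise ValueError("simplex_ls requires finite inputs")
    W, R = _solvers.simplex_ls_batch(target[None, :], basis, penalty)
    return W[0], float(R[0])


@dataclass(frozen=True)
class Decomposition:
    """Simplex weights of one field over the model archetypes."""

    weights: np.ndarray  # fractions, sum to 1
    rss: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        if self.rss < 0:
            raise ValueError("rss must be >= 0")
        object.__setattr__(self, "weights", w)

    @property
    def percent(self) -> np.ndarray:
        """Weights scaled to percent (sum to 100)."""
        return self.weights * 100.0


@dataclass(frozen=True)
class ArchetypeModel:
    """K archetype vectors on the shared binocular grid plus fit metadata."""

    k: int
    Z: np.ndarray  # (K, 52)
    locations: tuple[str, ...] = SHARED_NAMES
    mean_weights: np.ndarray | None = None  # descending; defines archetype order
    rss: float = float("nan")
    restarts: int = 0
    iterations: int = 0
    rss_history: tuple[float, ...] = ()
    penalty: float = DEFAULT_PENALTY
    tol: float = DEFAULT_TOL
    max_iter: int = DEFAULT_MAX_ITER
    seed: int | None = None
    n_train: int = 0

    def __post_init__(self) -> None:
        Z = np.asarray(self.Z, dtype=float)
        if Z.shape != (self.k, len(self.locations)):
            raise ValueError(f"Z shape {Z.shape} does not match K={self.k}")
        if np.any(Z < -1e-9) or np.any(Z > BINOC_MAX_DB + 1e-9):
            raise ValueError(f"archetype values outside [0, {BINOC_MAX_DB:.3f}] dB")
        object.__setattr__(self, "Z", Z)

    def to_json(self) -> str:
        payload = {
            "schema_version": _MODEL_SCHEMA_VERSION,
            "grid": list(self.locations),
            "k": self.k,
            "Z": [list(row) for row in self.Z],
            "mean_weights": None
            if self.mean_weights is None
            else list(np.asarray(self.mean_weights, dtype=float)),
            "fit": {
                "rss": self.rss,
                "restarts": self.restarts,
                "iterations": self.iterations,
                "rss_history": list(self.rss_history),
                "penalty": self.penalty,
                "tol": self.tol,
                "max_iter": self.max_iter,
                "seed": self.seed,
                "n_train": self.n_train,
            },
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ArchetypeModel":
        d = json.loads(text)
        if d.get("schema_version") != _MODEL_SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema: {d.get('schema_version')}")
        fit = d.get("fit", {})
        return cls(
            k=d["k"],
            Z=np.array(d["Z"], dtype=float),
            locations=tuple(d["grid"]),
            mean_weights=None
            if d.get("mean_weights") is None
            else np.array(d["mean_weights"], dtype=float),
            rss=fit.get("rss", float("nan")),
            restarts=fit.get("restarts", 0),
            iterations=fit.get("iterations", 0),
            rss_history=tuple(fit.get("rss_history", ())),
            penalty=fit.get("penalty", DEFAULT_PENALTY),
            tol=fit.get("tol", DEFAULT_TOL),
            max_iter=fit.get("max_iter", DEFAULT_MAX_ITER),
            seed=fit.get("seed"),
            n_train=fit.get("n_train", 0),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "ArchetypeModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _as_matrix(X) -> np.ndarray:
    X = np.ascontiguousarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("expected a 2-D data matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("data matrix contains non-finite values")
    return X


def _single_fit(X, gram_X, tt_X, k, rng, max_iter, tol, penalty):
    """One restart of the alternating optimization. Returns (Z, W, rss, history)."""
    n, d = X.shape
    idx0 = rng.choice(n, size=k, replace=False)
    Z = X[idx0].copy()
    prev_Z = Z
    prev_W = None
    prev_rss = math.inf
    history: list[float] = []
    iters = 0
    for it in range(max_iter):
        iters = it + 1
        # W-step: project every data row onto the hull of the archetypes
        W, res = _solvers.simplex_ls_gram(
            Z @ Z.T, np.ascontiguousarray(X @ Z.T), tt_X, penalty
        )
        # archetype starved of weight: reseed it at the worst-reconstructed point
        starved = np.flatnonzero(W.sum(axis=0) < 1e-8)
        if starved.size:
            worst = np.argsort(res)[::-1]
            for rank, j in enumerate(starved):
                Z[j] = X[worst[rank % n]]
            log.info("reinitialized %d starved archetype(s)", starved.size)
            W, res = _solvers.simplex_ls_gram(
                Z @ Z.T, np.ascontiguousarray(X @ Z.T), tt_X, penalty
            )
        # Z-hat step: unconstrained LS solve of X ~ W Zhat
        Zhat, *_ = np.linalg.lstsq(W, X, rcond=None)
        # C-step: express each Zhat row as a convex combination of data rows
        C, _ = _solvers.simplex_ls_gram(
            gram_X,
            np.ascontiguousarray(Zhat @ X.T),
            np.einsum("ij,ij->i", Zhat, Zhat),
            penalty,
        )
        Z_new = C @ X
        rss = float(np.sum((X - W @ Z_new) ** 2))
        if rss > prev_rss * (1.0 + 1e-12):
            # alternating step failed to improve; keep the previous state
            Z, W, rss = prev_Z, prev_W, prev_rss
            break
        history.append(rss)
        Z = Z_new
        prev_Z, prev_W = Z, W
        if prev_rss < math.inf and (prev_rss - rss) < tol * max(prev_rss, 1e-30):
            prev_rss = rss
            break
        prev_rss = rss
    # final W-step against the final archetypes (never increases the RSS)
    W, _ = _solvers.simplex_ls_gram(
        Z @ Z.T, np.ascontiguousarray(X @ Z.T), tt_X, penalty
    )
    rss = float(np.sum((X - W @ Z) ** 2))
    if history and rss > history[-1] * (1.0 + 1e-9):
        rss = history[-1]
    else:
        history.append(rss)
    return Z, W, rss, history, iters


def fit_archetypes(
    X,
    k: int,
    *,
    restarts: int = DEFAULT_RESTARTS,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    penalty: float = DEFAULT_PENALTY,
    seed: int | None = None,
    locations: Sequence[str] | None = None,
) -> ArchetypeModel:
    """Fit K archetypes by alternating optimization over seeded restarts.

    Every restart initializes the composition matrix from K distinct random
    data points and alternates W-step / unconstrained Z-hat / C-step until
    the relative RSS improvement drops below ``tol``.  The restart with the
    lowest training RSS wins; archetypes are ordered by descending mean
    training weight.
    """
    X = _as_matrix(X)
    n, d = X.shape
    if not n > k >= 1:
        raise ValueError(f"need n > K >= 1 (n={n}, K={k})")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    loc_names = tuple(locations) if locations is not None else (
        SHARED_NAMES if d == len(SHARED_NAMES) else tuple(f"v{i}" for i in range(d))
    )
    gram_X = np.ascontiguousarray(X @ X.T)
    tt_X = np.einsum("ij,ij->i", X, X)
    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(restarts):
        rng = np.random.default_rng(child)
        Z, W, rss, history, iters = _single_fit(
            X, gram_X, tt_X, k, rng, max_iter, tol, penalty
        )
        if best is None or rss < best[2]:
            best = (Z, W, rss, history, iters)
    Z, W, rss, history, iters = best
    mean_w = W.mean(axis=0)
    order = np.argsort(-mean_w, kind="stable")
    return ArchetypeModel(
        k=k,
        Z=np.clip(Z[order], 0.0, BINOC_MAX_DB),
        locations=loc_names,
        mean_weights=mean_w[order],
        rss=rss,
        restarts=restarts,
        iterations=iters,
        rss_history=tuple(history),
        penalty=penalty,
        tol=tol,
        max_iter=max_iter,
        seed=seed,
        n_train=n,
    )


def decompose(model: ArchetypeModel, ivf) -> Decomposition:
    """Decompose one integrated field into simplex weights over the archetypes."""
    if isinstance(ivf, IntegratedVF):
        if tuple(model.locations) != SHARED_NAMES:
            raise ValueError("model grid does not match the 52-location binocular grid")
        vec = ivf.vector()
    else:
        vec = np.asarray(ivf, dtype=float).ravel()
        if vec.size != len(model.locations):
            raise ValueError(
                f"field length {vec.size} does not match model grid "
                f"({len(model.locations)})"
            )
    w, rss = simplex_ls(vec, model.Z, model.penalty)
    return Decomposition(weights=w, rss=rss)


def decompose_matrix(model: ArchetypeModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized decomposition of many fields; returns (weights, residuals)."""
    X = _as_matrix(X)
    if X.shape[1] != len(model.locations):
        raise ValueError("field width does not match model grid")
    return _solvers.simplex_ls_batch(X, model.Z, model.penalty)


@dataclass(frozen=True)
class CVResult:
    """Per-fold validation scores for every candidate archetype count."""

    k_values: tuple[int, ...]
    scores: Mapping[int, np.ndarray]  # k -> (folds,) validation scores
    folds: int
    seed: int | None
    fold_assignment: np.ndarray = field(repr=False, default=None)
    normalization: str = CV_NORMALIZATION

    def __post_init__(self) -> None:
        for k in self.k_values:
            arr = np.asarray(self.scores[k], dtype=float)
            if arr.shape != (self.folds,):
                raise ValueError(f"expected {self.folds} scores for K={k}")
            if np.any(arr < 0):
                raise ValueError("validation scores must be >= 0")

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """All (k, score) observations, k-major then fold order."""
        ks, sc = [], []
        for k in self.k_values:
            for s in self.scores[k]:
                ks.append(k)
                sc.append(s)
        return np.array(ks, dtype=float), np.array(sc, dtype=float)


def crossvalidate_k(
    X,
    k_min: int = 2,
    k_max: int = 17,
    folds: int = 10,
    restarts: int = DEFAULT_RESTARTS,
    seed: int | None = None,
    *,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    penalty: float = DEFAULT_PENALTY,
) -> CVResult:
    """K-fold cross-validation of the archetype count over ``[k_min, k_max]``.

    Patients are partitioned into folds once (seeded) and the partition is
    reused for every candidate K.  The validation score of a (K, fold) cell
    is the mean squared reconstruction residual per validation field.
    Restart seeds are drawn from a stream independent of the fold stream,
    so changing ``restarts`` never changes the partition.
    """
    X = _as_matrix(X)
    n = X.shape[0]
    if not (n >= folds > 1):
        raise ValueError(f"need n >= folds > 1 (n={n}, folds={folds})")
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    if k_max < k_min:
        raise ValueError("k_max must be >= k_min")
    ss = np.random.SeedSequence(seed)
    fold_ss, fit_ss = ss.spawn(2)
    perm = np.random.default_rng(fold_ss).permutation(n)
    fold_assignment = np.empty(n, dtype=int)
    fold_assignment[perm] = np.arange(n) % folds
    min_train = min(int(np.sum(fold_assignment != f)) for f in range(folds))
    if min_train <= k_max:
        raise ValueError(
            f"smallest training split ({min_train}) must exceed k_max ({k_max})"
        )
    k_values = tuple(range(k_min, k_max + 1))
    fit_children = iter(fit_ss.spawn(len(k_values) * folds))
    scores: dict[int, np.ndarray] = {}
    for k in k_values:
        per_fold = np.empty(folds)
        for f in range(folds):
            child = next(fit_children)
            train = X[fold_assignment != f]
            val = X[fold_assignment == f]
            Z = _cv_fit(train, k, restarts, max_iter, tol, penalty, child)
            _, res = _solvers.simplex_ls_batch(val, Z, penalty)
            per_fold[f] = float(res.mean())
        scores[k] = per_fold
        log.info("cv K=%d: median score %.4f", k, float(np.median(per_fold)))
    return CVResult(
        k_values=k_values,
        scores=scores,
        folds=folds,
        seed=seed,
        fold_assignment=fold_assignment,
    )


def _cv_fit(train, k, restarts, max_iter, tol, penalty, seed_seq):
    """Best-restart archetype matrix for one CV cell (internal, seeded)."""
    gram = np.ascontiguousarray(train @ train.T)
    tt = np.einsum("ij,ij->i", train, train)
    best = None
    for child in seed_seq.spawn(restarts):
        rng = np.random.default_rng(child)
        Z, _, rss, _, _ = _single_fit(train, gram, tt, k, rng, max_iter, tol, penalty)
        if best is None or rss < best[1]:
            best = (Z, rss)
    return best[0]


def select_k(cv: CVResult) -> int:
    """Choose the archetype count by the BIC slope criterion.

    For each candidate K, pool all fold scores at counts >= K and compare,
    via BIC under a Gaussian likelihood, a linear score-vs-count model
    against a constant model.  The smallest K whose BIC difference
    (linear minus constant) is positive wins: no further slope is
    warranted.  Falls back to ``k_max`` (with a warning) if the scores keep
    decreasing over the whole range, and to ``k_min`` if all scores are
    identical.
    """
    ks = cv.k_values
    if len(ks) < 3:
        raise ValueError("select_k needs at least 3 consecutive K values")
    pooled_k, pooled_s = cv.pooled()
    if np.ptp(pooled_s) == 0.0:
        log.warning("select_k: all scores identical; returning k_min=%d", ks[0])
        return ks[0]
    for k_cand in ks[:-1]:
        mask = pooled_k >= k_cand
        x = pooled_k[mask]
        y = pooled_s[mask]
        n_obs = x.size
        slope, intercept = np.polyfit(x, y, 1)
        rss1 = float(np.sum((y - (intercept + slope * x)) ** 2))
        rss0 = float(np.sum((y - y.mean()) ** 2))
        eps = 1e-300
        bic1 = n_obs * math.log(max(rss1, eps) / n_obs) + 2.0 * math.log(n_obs)
        bic0 = n_obs * math.log(max(rss0, eps) / n_obs) + 1.0 * math.log(n_obs)
        if bic1 - bic0 > 0.0:
            return int(k_cand)
    log.warning(
        "select_k: scores still decreasing at k_max=%d; returning it", ks[-1]
    )
    return int(ks[-1])
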