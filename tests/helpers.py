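"""Shared test utilities: independent oracles and field constructors."""

from __future__ import annotations

import datetime as dt
import itertools

import numpy as np

from vfarch.core import MonocularVF, VFPair, grid_24_2


def simplex_oracle(target: np.ndarray, basis: np.ndarray):
    """Exact brute-force solution of min ||t - w'B||^2, w in the simplex.

    Enumerates every support subset, solves the equality-constrained KKT
    system on it, and keeps the feasible candidate with the smallest
    objective.  Exact for small m; fully independent of the package
    solver's NNLS/active-set route.
    """
    basis = np.atleast_2d(np.asarray(basis, dtype=float))
    target = np.asarray(target, dtype=float).ravel()
    m = basis.shape[0]
    G = basis @ basis.T
    h = basis @ target
    best_w, best_f = None, np.inf
    for r in range(1, m + 1):
        for S in itertools.combinations(range(m), r):
            S = list(S)
            k = len(S)
            K = np.zeros((k + 1, k + 1))
            rhs = np.zeros(k + 1)
            K[:k, :k] = 2.0 * G[np.ix_(S, S)]
            K[:k, k] = -1.0
            K[k, :k] = 1.0
            rhs[:k] = 2.0 * h[S]
            rhs[k] = 1.0
            try:
                sol = np.linalg.solve(K, rhs)
            except np.linalg.LinAlgError:
                continue
            wS = sol[:k]
            if wS.min() < -1e-12:
                continue
            w = np.zeros(m)
            w[S] = np.clip(wS, 0.0, None)
            w /= w.sum()
            f = float(np.sum((target - w @ basis) ** 2))
            if f < best_f:
                best_f, best_w = f, w
    return best_w, best_f


def mono_from_fn(
    fn,
    eye: str = "right",
    patient_id: str = "T",
    test_date: dt.date = dt.date(2020, 1, 1),
    fp: float = 0.01,
    fn_rate: float = 0.01,
    fl: float = 0.01,
    foveal: float = 33.0,
) -> MonocularVF:
    """Build a MonocularVF whose sensitivity at (x, y) is ``fn(x, y)``."""
    sens = {loc: float(fn(loc.x, loc.y)) for loc in grid_24_2(eye)}
    return MonocularVF(
        patient_id=patient_id,
        eye=eye,
        test_date=test_date,
        sensitivities=sens,
        foveal_db=foveal,
        fp_rate=fp,
        fn_rate=fn_rate,
        fl_rate=fl,
    )


def constant_mono(value: float, eye: str = "right", **kw) -> MonocularVF:
    return mono_from_fn(lambda x, y: value, eye=eye, **kw)


def constant_pair(
    r_value: float,
    l_value: float,
    patient_id: str = "T",
    test_date: dt.date = dt.date(2020, 1, 1),
    **kw,
) -> VFPair:
    return VFPair(
        right=constant_mono(r_value, "right", patient_id=patient_id, test_date=test_date, **kw),
        left=constant_mono(l_value, "left", patient_id=patient_id, test_date=test_date, **kw),
    )
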