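"""Ground-truth generators for every input the pipeline consumes.

Monocular pairs are built so that their binocular integration is a noisy
convex mixture of known defect templates; questionnaire responses are drawn
from a known proportional-odds model.  All generators are deterministic
given (parameters, seed), with one child random stream per patient so that
enlarging the cohort preserves the earlier patients' draws.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    BLIND_SPOTS,
    LEFT,
    RIGHT,
    SHARED_GRID,
    GridLocation,
    MonocularVF,
    VFPair,
    grid_24_2,
    normalize_eye,
)

# Hill-of-vision model for a normal monocular field.
NORMAL_PEAK_DB = 34.0
ECCENTRICITY_SLOPE = 0.3  # dB per degree of eccentricity
AGE_SLOPE = 0.05  # dB per year beyond the reference age
AGE_REF = 45.0
FOVEAL_PEAK_DB = 35.0
DEFAULT_NOISE_DB = 1.5
MONO_CAP_DB = 40.0

_SQRT2 = math.sqrt(2.0)

DEFAULT_VISIT_DATES = (_dt.date(2020, 1, 15), _dt.date(2021, 6, 15))


def normal_mono_value(x: float, y: float, age: float = AGE_REF) -> float:
    """Noise-free normal monocular sensitivity at one location."""
    return NORMAL_PEAK_DB - ECCENTRICITY_SLOPE * math.hypot(x, y) - AGE_SLOPE * (age - AGE_REF)


def normal_monocular_vf(
    age: float,
    eye: str,
    seed=None,
    *,
    noise_sigma: float = DEFAULT_NOISE_DB,
    patient_id: str = "synthetic",
    test_date: _dt.date = DEFAULT_VISIT_DATES[0],
    rng: np.random.Generator | None = None,
) -> MonocularVF:
    """A normal monocular 24-2 test drawn from the hill-of-vision model.

    ``s(x, y) = 34 - 0.3 * sqrt(x^2 + y^2) - 0.05 * (age - 45) + eps`` with
    eps ~ N(0, noise_sigma^2), clamped to [0, 40]; the eye's two blind-spot
    locations are 0; reliability rates are Beta(2, 30) draws.
    """
    if not 18.0 <= age <= 100.0:
        raise ValueError(f"age outside [18, 100]: {age}")
    eye = normalize_eye(eye)
    if rng is None:
        rng = np.random.default_rng(seed)
    grid = grid_24_2(eye)
    noise = rng.normal(0.0, 1.0, size=len(grid)) * noise_sigma
    blind = set(BLIND_SPOTS[eye])
    sens = {}
    for loc, eps in zip(grid, noise):
        if loc in blind:
            sens[loc] = 0.0
        else:
            sens[loc] = float(np.clip(normal_mono_value(loc.x, loc.y, age) + eps, 0.0, MONO_CAP_DB))
    foveal = float(
        np.clip(
            FOVEAL_PEAK_DB - AGE_SLOPE * (age - AGE_REF) + rng.normal(0.0, 1.0) * noise_sigma,
            0.0,
            MONO_CAP_DB,
        )
    )
    fp, fn, fl = rng.beta(2.0, 30.0, size=3)
    return MonocularVF(
        patient_id=patient_id,
        eye=eye,
        test_date=test_date,
        sensitivities=sens,
        foveal_db=foveal,
        fp_rate=float(min(fp, 0.10)),
        fn_rate=float(min(fn, 0.10)),
        fl_rate=float(fl),
    )


def _binocular_normal_vector() -> np.ndarray:
    """Noise-free age-45 binocular normal over the 52 shared locations."""
    return np.array(
        [_SQRT2 * normal_mono_value(l.x, l.y) for l in SHARED_GRID]
    )


TEMPLATE_NAMES = (
    "normal",
    "superior_hemifield",
    "inferior_hemifield",
    "superior_paracentral",
    "general_depression",
    "right_blindspot_region",
)


def template_library() -> dict[str, np.ndarray]:
    """Six fixed binocular defect patterns (52-vectors, canonical order)."""
    base = _binocular_normal_vector()
    xs = np.array([l.x for l in SHARED_GRID])
    ys = np.array([l.y for l in SHARED_GRID])
    lib = {
        "normal": base.copy(),
        "superior_hemifield": base - 20.0 * (ys > 0),
        "inferior_hemifield": base - 20.0 * (ys < 0),
        "superior_paracentral": base - 15.0 * ((np.abs(xs) <= 9) & (ys >= 3) & (ys <= 9)),
        "general_depression": base - 15.0,
        "right_blindspot_region": base - 20.0 * (np.isin(xs, (9, 15, 21)) & (np.abs(ys) <= 9)),
    }
    return {name: np.clip(vec, 0.0, None) for name, vec in lib.items()}


def template_matrix(k_true: int) -> tuple[tuple[str, ...], np.ndarray]:
    lib = template_library()
    if not 1 <= k_true <= len(lib):
        raise ValueError(f"k_true must be in [1, {len(lib)}]")
    names = TEMPLATE_NAMES[:k_true]
    return names, np.vstack([lib[n] for n in names])


@dataclass
class SyntheticTruth:
    """Per-patient ground truth of a simulated cohort."""

    patient_ids: tuple[str, ...]
    template_names: tuple[str, ...]
    weights: np.ndarray  # (n, k_true), simplex rows
    noise_sigma: float
    dirichlet_alpha: float
    seed: int | None
    ages: np.ndarray
    genders: np.ndarray  # 0/1
    foveal_binoc_db: np.ndarray
    beta: dict | None = None  # ordinal coefficients used for responses
    cutpoints: list | None = None

    def target_matrix(self) -> np.ndarray:
        """Noise-free binocular targets T = W @ templates."""
        _, T = template_matrix(len(self.template_names))
        return self.weights @ T

    def to_json(self) -> str:
        return json.dumps(
            {
                "patient_ids": list(self.patient_ids),
                "template_names": list(self.template_names),
                "weights": [list(r) for r in self.weights],
                "noise_sigma": self.noise_sigma,
                "dirichlet_alpha": self.dirichlet_alpha,
                "seed": self.seed,
                "ages": list(self.ages),
                "genders": [int(g) for g in self.genders],
                "foveal_binoc_db": list(self.foveal_binoc_db),
                "beta": self.beta,
                "cutpoints": self.cutpoints,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            patient_ids=tuple(d["patient_ids"]),
            template_names=tuple(d["template_names"]),
            weights=np.array(d["weights"], dtype=float),
            noise_sigma=d["noise_sigma"],
            dirichlet_alpha=d["dirichlet_alpha"],
            seed=d["seed"],
            ages=np.array(d["ages"], dtype=float),
            genders=np.array(d["genders"], dtype=int),
            foveal_binoc_db=np.array(d["foveal_binoc_db"], dtype=float),
            beta=d.get("beta"),
            cutpoints=d.get("cutpoints"),
        )


@dataclass
class SimulatedCohort:
    """Long-format VF rows, per-test metadata and the generating truth."""

    vf: pd.DataFrame
    meta: pd.DataFrame
    truth: SyntheticTruth

    def write(self, outdir) -> dict[str, str]:
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "vf": os.path.join(outdir, "vf.csv"),
            "meta": os.path.join(outdir, "meta.csv"),
            "truth": os.path.join(outdir, "truth.json"),
        }
        self.vf.to_csv(paths["vf"], index=False)
        self.meta.to_csv(paths["meta"], index=False)
        with open(paths["truth"], "w") as fh:
            fh.write(self.truth.to_json())
        return paths


def _monocular_rows(pid, eye, date, values: Mapping[GridLocation, float]):
    return [
        {
            "patient_id": pid,
            "eye": "OD" if eye == RIGHT else "OS",
            "test_date": date.isoformat(),
            "x_deg": loc.x,
            "y_deg": loc.y,
            "sensitivity_db": float(values[loc]),
        }
        for loc in grid_24_2(eye)
    ]


def simulate_cohort(
    n: int,
    k_true: int = 4,
    dirichlet_alpha: float = 1.0,
    noise_sigma: float = 1.0,
    seed: int | None = None,
    *,
    visit_dates: Sequence[_dt.date] = DEFAULT_VISIT_DATES,
    asymmetry: float = 0.0,
) -> SimulatedCohort:
    """Simulate paired monocular tests whose binocular integration is a noisy
    convex mixture of the first ``k_true`` templates.

    Per patient: simplex weights ~ Dirichlet(alpha), with every fifth
    patient forced near-pure (max weight >= 0.9) so the template vertices
    are attainable; binocular target ``T = w @ templates``; monocular
    fields ``R = L = T / sqrt(2)`` on the 52 shared locations plus
    independent per-eye noise, clamped to [0, 40].  The nasal-extension
    points are filled from the monocular normal.  Two reliable visits are
    emitted per patient so visit selection is exercised.  ``asymmetry`` in
    [0, 1) shifts defect mass from the left eye to the right eye for
    stress tests.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    names, templates = template_matrix(k_true)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)
    shared_index = {loc: i for i, loc in enumerate(SHARED_GRID)}

    vf_rows: list[dict] = []
    meta_rows: list[dict] = []
    weights = np.empty((n, k_true))
    ages = np.empty(n)
    genders = np.empty(n, dtype=int)
    foveal_true = np.empty(n)
    pids = tuple(f"P{i:05d}" for i in range(n))

    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        w = rng.dirichlet(np.full(k_true, dirichlet_alpha))
        if i % 5 == 0:  # force near-pure so hull vertices are touched by data
            t_idx = (i // 5) % k_true
            w = 0.08 * w
            w[t_idx] += 0.92
        weights[i] = w
        age = float(rng.uniform(50.0, 85.0))
        gender = int(rng.integers(0, 2))
        ages[i] = age
        genders[i] = gender
        T = w @ templates
        mono = T / _SQRT2
        # patient-level foveal deviation keeps foveal sensitivity from being
        # perfectly collinear with age in downstream regressions
        f_dev = float(rng.normal(0.0, 1.5))
        f_mono = float(
            np.clip(FOVEAL_PEAK_DB - AGE_SLOPE * (age - AGE_REF) + f_dev, 0.0, MONO_CAP_DB)
        )
        foveal_true[i] = math.hypot(f_mono, f_mono)
        for date in visit_dates:
            for eye in (RIGHT, LEFT):
                eye_scale = (1.0 + asymmetry) if eye == RIGHT else (1.0 - asymmetry)
                grid = grid_24_2(eye)
                eps = rng.normal(0.0, 1.0, size=len(grid)) * noise_sigma
                values = {}
                for loc, e in zip(grid, eps):
                    if loc in shared_index:
                        base = mono[shared_index[loc]] * eye_scale
                    else:  # unpaired nasal-extension point
                        base = normal_mono_value(loc.x, loc.y, age)
                    values[loc] = float(np.clip(base + e, 0.0, MONO_CAP_DB))
                f_eps = rng.normal(0.0, 1.0) * noise_sigma
                foveal = float(np.clip(f_mono + f_eps, 0.0, MONO_CAP_DB))
                fp, fn, fl = rng.beta(2.0, 30.0, size=3)
                vf_rows.extend(_monocular_rows(pids[i], eye, date, values))
                meta_rows.append(
                    {
                        "patient_id": pids[i],
                        "eye": "OD" if eye == RIGHT else "OS",
                        "test_date": date.isoformat(),
                        "fp_rate": round(float(min(fp, 0.10)), 6),
                        "fn_rate": round(float(min(fn, 0.10)), 6),
                        "fl_rate": round(float(fl), 6),
                        "foveal_db": foveal,
                        "age_years": round(age, 2),
                        "gender": gender,
                    }
                )

    truth = SyntheticTruth(
        patient_ids=pids,
        template_names=names,
        weights=weights,
        noise_sigma=noise_sigma,
        dirichlet_alpha=dirichlet_alpha,
        seed=seed,
        ages=ages,
        genders=genders,
        foveal_binoc_db=foveal_true,
    )
    return SimulatedCohort(
        vf=pd.DataFrame(vf_rows), meta=pd.DataFrame(meta_rows), truth=truth
    )


def simulate_neuro_pair(
    severity_db: float,
    seed=None,
    *,
    noise_sigma: float = DEFAULT_NOISE_DB,
    age: float = 65.0,
    patient_id: str = "neuro",
    test_date: _dt.date = DEFAULT_VISIT_DATES[0],
) -> VFPair:
    """A homonymous left-field defect pair: both eyes lose ``severity_db``
    at every ``x < 0`` location (clamped at 0)."""
    if severity_db <= 0:
        raise ValueError("severity_db must be > 0")
    rng = np.random.default_rng(seed)
    eyes = {}
    for eye in (RIGHT, LEFT):
        vf = normal_monocular_vf(
            age, eye, rng=rng, noise_sigma=noise_sigma,
            patient_id=patient_id, test_date=test_date,
        )
        sens = {
            loc: (max(0.0, v - severity_db) if loc.x < 0 else v)
            for loc, v in vf.sensitivities.items()
        }
        eyes[eye] = MonocularVF(
            patient_id=patient_id,
            eye=eye,
            test_date=test_date,
            sensitivities=sens,
            foveal_db=vf.foveal_db,
            fp_rate=vf.fp_rate,
            fn_rate=vf.fn_rate,
            fl_rate=vf.fl_rate,
        )
    return VFPair(right=eyes[RIGHT], left=eyes[LEFT])


def simulate_glaucoma_pair(
    seed=None,
    *,
    k_true: int = 4,
    noise_sigma: float = 1.0,
    dirichlet_alpha: float = 1.0,
    age: float = 65.0,
    patient_id: str = "glaucoma",
    test_date: _dt.date = DEFAULT_VISIT_DATES[0],
) -> VFPair:
    """One bilateral glaucoma-pattern pair (R = L = mixture / sqrt(2) + noise)."""
    rng = np.random.default_rng(seed)
    _, templates = template_matrix(k_true)
    w = rng.dirichlet(np.full(k_true, dirichlet_alpha))
    mono = (w @ templates) / _SQRT2
    shared_index = {loc: i for i, loc in enumerate(SHARED_GRID)}
    eyes = {}
    for eye in (RIGHT, LEFT):
        grid = grid_24_2(eye)
        eps = rng.normal(0.0, 1.0, size=len(grid)) * noise_sigma
        sens = {}
        for loc, e in zip(grid, eps):
            base = (
                mono[shared_index[loc]]
                if loc in shared_index
                else normal_mono_value(loc.x, loc.y, age)
            )
            sens[loc] = float(np.clip(base + e, 0.0, MONO_CAP_DB))
        fp, fn, fl = rng.beta(2.0, 30.0, size=3)
        eyes[eye] = MonocularVF(
            patient_id=patient_id,
            eye=eye,
            test_date=test_date,
            sensitivities=sens,
            foveal_db=float(np.clip(FOVEAL_PEAK_DB - AGE_SLOPE * (age - AGE_REF), 0, MONO_CAP_DB)),
            fp_rate=float(min(fp, 0.10)),
            fn_rate=float(min(fn, 0.10)),
            fl_rate=float(fl),
        )
    return VFPair(right=eyes[RIGHT], left=eyes[LEFT])


def default_cutpoints(levels: int, offset: float = 0.0) -> list[float]:
    """Evenly spread logistic cutpoints for an item with ``levels`` levels."""
    return [math.log(c / (levels - c)) + offset for c in range(1, levels)]


def predictor_frame(truth: SyntheticTruth) -> pd.DataFrame:
    """Per-patient predictors on the association scale: template weight
    percents (templates 2..k), age, gender, binocular foveal sensitivity."""
    cols = {}
    for j, name in enumerate(truth.template_names):
        if j == 0:
            continue
        cols[f"w_{name}"] = truth.weights[:, j] * 100.0
    cols["age"] = truth.ages
    cols["gender"] = truth.genders.astype(float)
    cols["foveal_binoc_db"] = truth.foveal_binoc_db
    return pd.DataFrame(cols, index=list(truth.patient_ids))


def simulate_qol(
    truth: SyntheticTruth,
    item_map,
    beta: Mapping[str, float],
    cutpoints: Mapping[int, Sequence[float]] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Ordinal questionnaire responses from a known proportional-odds model.

    The latent score per patient is ``eta = beta . x`` over the predictor
    frame columns; for an L-level item a "goodness" level g is drawn with
    ``P(g <= c) = logistic(theta_c - eta)`` so that larger eta means better
    responses.  The emitted raw level honours each item's declared
    direction.  ``cutpoints`` maps level counts to strictly increasing
    thresholds; by default thresholds are evenly spread logistic quantiles
    centred on the cohort mean of eta.

    Updates ``truth.beta`` / ``truth.cutpoints`` in place for provenance.
    """
    X = predictor_frame(truth)
    unknown = set(beta) - set(X.columns)
    if unknown:
        raise ValueError(f"beta names not in predictor frame: {sorted(unknown)}")
    eta = np.zeros(len(X))
    for name, b in beta.items():
        eta += float(b) * X[name].to_numpy()

    level_counts = sorted({item.levels for item in item_map.items.values()})
    cp: dict[int, np.ndarray] = {}
    for L in level_counts:
        if cutpoints is not None and L in cutpoints:
            arr = np.asarray(cutpoints[L], dtype=float)
        else:
            arr = np.array(default_cutpoints(L, offset=float(eta.mean())))
        if arr.shape != (L - 1,) or np.any(np.diff(arr) <= 0):
            raise ValueError(f"cutpoints for {L}-level items must be {L - 1} strictly increasing values")
        cp[L] = arr

    rng = np.random.default_rng(seed)
    rows = []
    for item in item_map.items.values():
        L = item.levels
        cum = 1.0 / (1.0 + np.exp(-(cp[L][:, None] - eta[None, :])))  # (L-1, n)
        probs = np.vstack([cum, np.ones((1, len(eta)))])
        probs[1:] -= cum
        u = rng.random(len(eta))
        goodness = (u[None, :] > np.cumsum(probs, axis=0)).sum(axis=0) + 1
        raw = (L + 1 - goodness) if item.level1_best else goodness
        for pid, lvl in zip(truth.patient_ids, raw):
            rows.append({"patient_id": pid, "item_id": item.id, "response_level": int(lvl)})
    truth.beta = {k: float(v) for k, v in beta.items()}
    truth.cutpoints = {int(L): list(map(float, v)) for L, v in cp.items()}
    return pd.DataFrame(rows)
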