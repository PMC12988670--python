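"""Questionnaire scoring, archetype-QoL ordinal regression and prediction.

Item responses are standardized to 0-100 (best answer = 100) with a linear
level-to-score mapping; subscale scores are unweighted means of their
answered member items.  Each QoL aspect (a subscale, or a standalone item)
is modelled with a cumulative-logit proportional-odds regression on
archetype weight percents (archetype 1, the normal pattern, is excluded as
the reference) plus age, gender and binocular foveal sensitivity.  A
positive coefficient means better scores.  Significance uses a Bonferroni
threshold over the whole ensemble of aspects.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.api import Logit, add_constant
from statsmodels.miscmodels.ordinal_model import OrderedModel

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_N_TESTS = 43


@dataclass(frozen=True)
class Item:
    id: str
    levels: int
    level1_best: bool = True
    subscale: str | None = None
    missing_codes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError(f"item {self.id}: levels must be >= 2")


@dataclass(frozen=True)
class ItemMap:
    """Questionnaire structure: items, directions, subscale membership."""

    items: Mapping[str, Item]

    @property
    def subscales(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {}
        for item in self.items.values():
            if item.subscale is not None:
                out.setdefault(item.subscale, []).append(item.id)
        return {k: tuple(v) for k, v in out.items()}

    @property
    def aspects(self) -> tuple[str, ...]:
        """Modelled QoL aspects: subscales, then standalone items, stable order."""
        names: list[str] = []
        seen_sub: set[str] = set()
        for item in self.items.values():
            if item.subscale is not None:
                if item.subscale not in seen_sub:
                    seen_sub.add(item.subscale)
                    names.append(item.subscale)
            else:
                names.append(item.id)
        return tuple(names)

    @classmethod
    def from_dict(cls, data: dict) -> "ItemMap":
        items: dict[str, Item] = {}
        for row in data["items"]:
            item = Item(
                id=row["id"],
                levels=int(row["levels"]),
                level1_best=bool(row.get("level1_best", True)),
                subscale=row.get("subscale"),
                missing_codes=tuple(row.get("missing_codes", ())),
            )
            if item.id in items:
                raise ValueError(f"duplicate item id: {item.id}")
            items[item.id] = item
        return cls(items=items)

    @classmethod
    def from_yaml(cls, path) -> "ItemMap":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "ItemMap":
        text = (
            importlib.resources.files("vfarch.data")
            .joinpath("items_default.yaml")
            .read_text()
        )
        return cls.from_dict(yaml.safe_load(text))


def score_items(raw: pd.DataFrame, item_map: ItemMap) -> pd.DataFrame:
    """Standardize raw ordinal responses to 0-100 item scores.

    ``raw`` is long format with columns patient_id, item_id, response_level.
    After direction alignment (level 1 = best), level l of an L-level item
    scores ``100 * (L - l) / (L - 1)``; declared missing codes map to NaN.
    Returns a patients x items frame covering every item in the map.
    """
    required = {"patient_id", "item_id", "response_level"}
    if not required.issubset(raw.columns):
        raise ValueError(f"response table must have columns {sorted(required)}")
    unknown = set(raw["item_id"]) - set(item_map.items)
    if unknown:
        raise ValueError(f"responses reference unknown items: {sorted(unknown)}")
    scores: dict[tuple[str, str], float] = {}
    for pid, iid, lvl in raw[["patient_id", "item_id", "response_level"]].itertuples(index=False):
        item = item_map.items[iid]
        if pd.isna(lvl):
            continue
        lvl = int(lvl)
        if lvl in item.missing_codes:
            continue
        if not 1 <= lvl <= item.levels:
            raise ValueError(
                f"item {iid}: response level {lvl} outside 1..{item.levels}"
            )
        aligned = lvl if item.level1_best else item.levels + 1 - lvl
        scores[(pid, iid)] = 100.0 * (item.levels - aligned) / (item.levels - 1)
    patients = pd.unique(raw["patient_id"])
    out = pd.DataFrame(index=patients, columns=list(item_map.items), dtype=float)
    for (pid, iid), v in scores.items():
        out.at[pid, iid] = v
    out.index.name = "patient_id"
    return out


def score_subscales(item_scores: pd.DataFrame, item_map: ItemMap) -> pd.DataFrame:
    """Unweighted mean of answered member items per subscale (NaN if none)."""
    subs = item_map.subscales
    out = pd.DataFrame(index=item_scores.index, columns=list(subs), dtype=float)
    for name, members in subs.items():
        missing_members = [m for m in members if m not in item_scores.columns]
        if missing_members:
            raise ValueError(f"subscale {name}: unknown items {missing_members}")
        out[name] = item_scores[list(members)].mean(axis=1, skipna=True)
    out.index.name = "patient_id"
    return out


def aspect_scores(item_scores: pd.DataFrame, item_map: ItemMap) -> pd.DataFrame:
    """Scores for each modelled aspect: subscales plus standalone items."""
    subs = score_subscales(item_scores, item_map)
    cols = {}
    for name in item_map.aspects:
        if name in subs.columns:
            cols[name] = subs[name]
        else:
            cols[name] = item_scores[name]
    out = pd.DataFrame(cols)
    out.index.name = "patient_id"
    return out


def bonferroni_threshold(alpha: float = DEFAULT_ALPHA, n_tests: int = DEFAULT_N_TESTS) -> float:
    """Per-comparison threshold for a family-wise alpha over n_tests aspects."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class AspectModel:
    """Serializable proportional-odds (or binary-logit fallback) fit."""

    aspect: str
    kind: str  # "ordinal" | "binary"
    categories: list[float]  # observed score values, ascending
    thresholds: list[float]  # cumulative-logit cutpoints (ordinal) or [-intercept]
    beta: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, float]
    n_obs: int
    converged: bool = True

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        eta = np.zeros(len(X))
        for name, b in self.beta.items():
            eta += b * X[name].to_numpy(dtype=float)
        return eta

    def category_probs(self, X: pd.DataFrame) -> np.ndarray:
        """(n, n_categories) probabilities; rows sum to 1."""
        eta = self.linear_predictor(X)
        th = np.asarray(self.thresholds, dtype=float)
        cum = 1.0 / (1.0 + np.exp(-(th[:, None] - eta[None, :])))  # (C-1, n)
        probs = np.vstack([cum, np.ones((1, len(eta)))])
        probs[1:] -= cum
        return np.clip(probs.T, 0.0, 1.0)

    def expected_score(self, X: pd.DataFrame) -> np.ndarray:
        probs = self.category_probs(X)
        return probs @ np.asarray(self.categories, dtype=float)


@dataclass
class AssociationResult:
    """Per aspect x predictor coefficients, Wald inference and flags."""

    table: pd.DataFrame  # columns: aspect, predictor, coef, se, p, significant
    models: dict[str, AspectModel]
    alpha: float
    n_tests: int
    notes: list[str] = field(default_factory=list)

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(self.alpha, self.n_tests)

    def wide(self, value: str = "coef") -> pd.DataFrame:
        """Aspect x predictor matrix of one statistic (heatmap-style)."""
        return self.table.pivot(index="aspect", columns="predictor", values=value)

    def models_to_json(self) -> str:
        payload = {
            "alpha": self.alpha,
            "n_tests": self.n_tests,
            "models": {
                name: {
                    "aspect": m.aspect,
                    "kind": m.kind,
                    "categories": m.categories,
                    "thresholds": m.thresholds,
                    "beta": m.beta,
                    "se": m.se,
                    "pvalues": m.pvalues,
                    "n_obs": m.n_obs,
                    "converged": m.converged,
                }
                for name, m in self.models.items()
            },
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def models_from_json(cls, text: str) -> dict[str, AspectModel]:
        data = json.loads(text)
        return {
            name: AspectModel(**spec) for name, spec in data["models"].items()
        }


def _fit_one_aspect(
    aspect: str, y: pd.Series, X: pd.DataFrame
) -> AspectModel | None:
    values = np.sort(y.unique())
    if values.size < 2:
        log.warning("aspect %s: fewer than 2 distinct scores; skipped", aspect)
        return None
    if values.size < 3:
        # binary fallback: model P(best of the two observed values)
        log.info("aspect %s: only 2 distinct scores; binary logistic fallback", aspect)
        yb = (y == values[-1]).astype(float)
        res = Logit(yb, add_constant(X, has_constant="add")).fit(disp=False, maxiter=200)
        beta = {c: float(res.params[c]) for c in X.columns}
        return AspectModel(
            aspect=aspect,
            kind="binary",
            categories=[float(v) for v in values],
            thresholds=[-float(res.params["const"])],
            beta=beta,
            se={c: float(res.bse[c]) for c in X.columns},
            pvalues={c: float(res.pvalues[c]) for c in X.columns},
            n_obs=int(res.nobs),
            converged=bool(res.mle_retvals.get("converged", True)),
        )
    y_cat = pd.Categorical(y, categories=list(values), ordered=True)
    model = OrderedModel(y_cat, X, distr="logit")
    res = model.fit(method="bfgs", maxiter=500, disp=False)
    converged = bool(res.mle_retvals.get("converged", True))
    if not converged:
        log.warning("aspect %s: ordinal fit did not converge", aspect)
    k = X.shape[1]
    thresholds = model.transform_threshold_params(res.params.to_numpy())[1:-1]
    return AspectModel(
        aspect=aspect,
        kind="ordinal",
        categories=[float(v) for v in values],
        thresholds=[float(t) for t in thresholds],
        beta={c: float(res.params[c]) for c in X.columns},
        se={c: float(res.bse[c]) for c in X.columns},
        pvalues={c: float(res.pvalues[c]) for c in X.columns},
        n_obs=int(res.nobs),
        converged=converged,
    )


def fit_association(
    aspects: pd.DataFrame,
    predictors: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    n_tests: int | None = None,
) -> AssociationResult:
    """Fit one proportional-odds model per QoL aspect.

    ``aspects``: patients x aspect scores (0-100, NaN allowed per aspect).
    ``predictors``: patients x predictors -- archetype weight percents
    (excluding archetype 1) and covariates.  Patients with missing
    predictor values are dropped with a notice.  ``n_tests`` defaults to 43
    (the shipped ensemble size) when the aspect count matches the default
    map, otherwise to the number of aspect columns.
    """
    common = aspects.index.intersection(predictors.index)
    if len(common) < 10:
        raise ValueError(f"too few overlapping patients: {len(common)}")
    X_all = predictors.loc[common].astype(float)
    if X_all.isna().any().any():
        bad = X_all.index[X_all.isna().any(axis=1)]
        log.warning("dropping %d patient(s) with missing covariates", len(bad))
        X_all = X_all.drop(index=bad)
    if n_tests is None:
        n_tests = DEFAULT_N_TESTS if aspects.shape[1] <= DEFAULT_N_TESTS else aspects.shape[1]
    threshold = bonferroni_threshold(alpha, n_tests)
    rows = []
    models: dict[str, AspectModel] = {}
    notes: list[str] = []
    for aspect in aspects.columns:
        y = aspects.loc[X_all.index, aspect].dropna()
        X = X_all.loc[y.index]
        try:
            fitted = _fit_one_aspect(aspect, y, X)
        except Exception as exc:  # separation / non-convergence is not fatal
            notes.append(f"{aspect}: fit failed ({exc})")
            log.warning("aspect %s: fit failed: %s", aspect, exc)
            continue
        if fitted is None:
            notes.append(f"{aspect}: fewer than 2 distinct scores; skipped")
            continue
        if not fitted.converged:
            notes.append(f"{aspect}: did not converge")
        models[aspect] = fitted
        for name in X.columns:
            p = fitted.pvalues[name]
            rows.append(
                {
                    "aspect": aspect,
                    "predictor": name,
                    "coef": fitted.beta[name],
                    "se": fitted.se[name],
                    "p": p,
                    "significant": bool(p < threshold),
                }
            )
    table = pd.DataFrame(rows, columns=["aspect", "predictor", "coef", "se", "p", "significant"])
    return AssociationResult(table=table, models=models, alpha=alpha, n_tests=n_tests, notes=notes)


def predict_qol(
    models: Mapping[str, AspectModel] | AssociationResult,
    predictors: pd.DataFrame,
    aspects: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Expected 0-100 score per patient and aspect under the fitted models.

    The expectation is the probability-weighted mean of the observed score
    categories, so predictions always lie within [min, max] observed values.
    """
    if isinstance(models, AssociationResult):
        models = models.models
    names = list(aspects) if aspects is not None else list(models)
    out = pd.DataFrame(index=predictors.index, columns=names, dtype=float)
    for name in names:
        m = models[name]
        missing = set(m.beta) - set(predictors.columns)
        if missing:
            raise ValueError(f"aspect {name}: predictors missing {sorted(missing)}")
        out[name] = m.expected_score(predictors)
    out.index.name = "patient_id"
    return out


def archetype_clinical_correlations(
    data: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson correlations between archetype weights and clinical variables.

    Returns ``(corr, pvalues, significant)`` over every unique column pair;
    Bonferroni is applied over the number of unique pairs.  Zero-variance
    columns get NaN correlations and are never flagged.
    """
    if len(data) < 3:
        raise ValueError("need at least 3 patients")
    cols = list(data.columns)
    corr = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pvals = pd.DataFrame(np.nan, index=cols, columns=cols)
    sig = pd.DataFrame(False, index=cols, columns=cols)
    n_pairs = len(cols) * (len(cols) - 1) // 2
    threshold = bonferroni_threshold(alpha, max(n_pairs, 1))
    for a, b in combinations(cols, 2):
        xa = data[a].to_numpy(dtype=float)
        xb = data[b].to_numpy(dtype=float)
        if np.ptp(xa) == 0.0 or np.ptp(xb) == 0.0:
            corr.loc[a, b] = corr.loc[b, a] = np.nan
            continue
        r, p = stats.pearsonr(xa, xb)
        corr.loc[a, b] = corr.loc[b, a] = r
        pvals.loc[a, b] = pvals.loc[b, a] = p
        flag = bool(p < threshold)
        sig.loc[a, b] = sig.loc[b, a] = flag
    for c in cols:
        if np.ptp(data[c].to_numpy(dtype=float)) == 0.0:
            corr.loc[c, c] = np.nan
    return corr, pvals, sig
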