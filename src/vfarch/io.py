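"""CSV/JSON readers and writers for the pipeline's plain-text artifacts."""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    LEFT,
    RIGHT,
    SHARED_NAMES,
    GridLocation,
    IntegratedVF,
    MonocularVF,
    VFPair,
    normalize_eye,
)

log = logging.getLogger(__name__)

VF_COLUMNS = ("patient_id", "eye", "test_date", "x_deg", "y_deg", "sensitivity_db")
META_COLUMNS = (
    "patient_id", "eye", "test_date",
    "fp_rate", "fn_rate", "fl_rate", "foveal_db", "age_years", "gender",
)


@dataclass
class ValidationReport:
    """Per-record validation errors collected while loading."""

    errors: list[str] = field(default_factory=list)

    def add(self, msg: str) -> None:
        self.errors.append(msg)
        log.warning("validation: %s", msg)

    def raise_if_strict(self, strict: bool) -> None:
        if strict and self.errors:
            raise ValueError(
                f"{len(self.errors)} validation error(s); first: {self.errors[0]}"
            )


def _parse_date(value) -> _dt.date:
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value))


def read_vf_csv(
    path,
    *,
    mirror_left: bool = False,
    strict: bool = False,
    report: ValidationReport | None = None,
) -> list[MonocularVF]:
    """Load long-format monocular tests, validating grid completeness.

    Rows are aggregated by (patient, eye, date).  Sensitivities below 0 dB
    are coerced to 0 at import.  ``mirror_left`` flips the x axis of
    left-eye rows for chart-mirrored exports.  Invalid tests are rejected
    individually (itemized in the report); ``strict`` raises instead.
    """
    df = pd.read_csv(path)
    missing = set(VF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if report is None:
        report = ValidationReport()
    tests: list[MonocularVF] = []
    for (pid, eye_code, date), grp in df.groupby(
        ["patient_id", "eye", "test_date"], sort=False
    ):
        label = f"{pid}/{eye_code}/{date}"
        try:
            eye = normalize_eye(eye_code)
        except ValueError as exc:
            report.add(f"{label}: {exc}")
            continue
        sens: dict[GridLocation, float] = {}
        dup = False
        for row in grp.itertuples(index=False):
            x = int(row.x_deg)
            if mirror_left and eye == LEFT:
                x = -x
            loc = GridLocation(x, int(row.y_deg))
            if loc in sens:
                report.add(f"{label}: duplicate location {loc.name} (line ~{row.Index if hasattr(row, 'Index') else '?'})")
                dup = True
                break
            v = float(row.sensitivity_db)
            if v < 0.0:
                v = 0.0  # "<0" imports coerced to 0
            sens[loc] = v
        if dup:
            continue
        try:
            tests.append(
                MonocularVF(
                    patient_id=str(pid),
                    eye=eye,
                    test_date=_parse_date(date),
                    sensitivities=sens,
                )
            )
        except ValueError as exc:
            report.add(str(exc))
    report.raise_if_strict(strict)
    return tests


def read_meta_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.copy()
    df["eye"] = df["eye"].map(normalize_eye)
    df["patient_id"] = df["patient_id"].astype(str)
    df["test_date"] = df["test_date"].astype(str)
    return df.set_index(["patient_id", "eye", "test_date"])


def attach_metadata(
    tests: list[MonocularVF],
    meta: pd.DataFrame,
    report: ValidationReport | None = None,
    strict: bool = False,
) -> list[MonocularVF]:
    """Fill reliability rates and foveal sensitivity from the metadata table."""
    if report is None:
        report = ValidationReport()
    out = []
    for t in tests:
        key = (t.patient_id, t.eye, t.test_date.isoformat())
        try:
            row = meta.loc[key]
        except KeyError:
            report.add(f"{key[0]}/{key[1]}/{key[2]}: no metadata row")
            continue
        if isinstance(row, pd.DataFrame):
            row = row.iloc[0]
        out.append(
            MonocularVF(
                patient_id=t.patient_id,
                eye=t.eye,
                test_date=t.test_date,
                sensitivities=t.sensitivities,
                foveal_db=float(row["foveal_db"]),
                fp_rate=float(row["fp_rate"]),
                fn_rate=float(row["fn_rate"]),
                fl_rate=float(row["fl_rate"]),
            )
        )
    report.raise_if_strict(strict)
    return out


def load_tests(
    vf_path,
    meta_path,
    *,
    mirror_left: bool = False,
    strict: bool = False,
    report: ValidationReport | None = None,
) -> list[MonocularVF]:
    if report is None:
        report = ValidationReport()
    tests = read_vf_csv(vf_path, mirror_left=mirror_left, report=report)
    meta = read_meta_csv(meta_path)
    out = attach_metadata(tests, meta, report=report)
    report.raise_if_strict(strict)
    return out


def pair_by_visit(
    tests: list[MonocularVF], report: ValidationReport | None = None
) -> dict[str, list[VFPair]]:
    """Group tests into same-visit right/left pairs per patient.

    Unpaired tests are reported and skipped.  Pair order follows first
    appearance in the input (stable), which select_analysis_visit relies on
    for tie-breaking.
    """
    if report is None:
        report = ValidationReport()
    by_visit: dict[tuple[str, _dt.date], dict[str, MonocularVF]] = {}
    order: list[tuple[str, _dt.date]] = []
    for t in tests:
        key = (t.patient_id, t.test_date)
        if key not in by_visit:
            by_visit[key] = {}
            order.append(key)
        if t.eye in by_visit[key]:
            report.add(f"{t.patient_id}/{t.eye}/{t.test_date}: duplicate test")
            continue
        by_visit[key][t.eye] = t
    pairs: dict[str, list[VFPair]] = {}
    for pid, date in order:
        eyes = by_visit[(pid, date)]
        if RIGHT in eyes and LEFT in eyes:
            pairs.setdefault(pid, []).append(VFPair(right=eyes[RIGHT], left=eyes[LEFT]))
        else:
            report.add(f"{pid}/{date}: unpaired visit (missing one eye)")
    return pairs


def ivf_frame(ivfs: list[IntegratedVF]) -> pd.DataFrame:
    """Wide one-row-per-patient frame: 52 location columns + summaries."""
    rows = []
    for ivf in ivfs:
        row: dict = {"patient_id": ivf.patient_id}
        vec = ivf.vector()
        row.update(dict(zip(SHARED_NAMES, vec)))
        row["ivf_ms"] = ivf.ivf_ms
        row["foveal_binoc_db"] = ivf.foveal_binoc_db
        rows.append(row)
    return pd.DataFrame(rows, columns=["patient_id", *SHARED_NAMES, "ivf_ms", "foveal_binoc_db"])


def write_ivf_csv(ivfs: list[IntegratedVF], path) -> None:
    ivf_frame(ivfs).to_csv(path, index=False)


def read_ivf_csv(path) -> tuple[list[str], np.ndarray, pd.DataFrame]:
    """Returns (patient_ids, n x 52 matrix in canonical order, full frame)."""
    df = pd.read_csv(path)
    missing = set(SHARED_NAMES) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing location columns, e.g. {sorted(missing)[:3]}")
    ids = [str(p) for p in df["patient_id"]]
    X = df[list(SHARED_NAMES)].to_numpy(dtype=float)
    return ids, X, df


def write_weights_csv(patient_ids, weights_percent: np.ndarray, rss: np.ndarray, path) -> None:
    """One row per patient: AT1..ATK weight percents plus reconstruction RSS."""
    k = weights_percent.shape[1]
    df = pd.DataFrame(weights_percent, columns=[f"AT{j + 1}" for j in range(k)])
    df.insert(0, "patient_id", list(patient_ids))
    df["rss"] = rss
    df.to_csv(path, index=False)


def read_weights_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["patient_id"] = df["patient_id"].astype(str)
    return df.set_index("patient_id")


def write_cv_csv(cv, path) -> None:
    rows = []
    for k in cv.k_values:
        for f, s in enumerate(cv.scores[k]):
            rows.append({"k": k, "fold": f, "score": s})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_qol_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "item_id", "response_level"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["patient_id"] = df["patient_id"].astype(str)
    return df


def write_manifest(path, command: str, params: dict, inputs: dict, outputs: dict, seed=None) -> None:
    """Machine-readable run manifest; deterministic for identical configs."""
    from . import __version__

    payload = {
        "command": command,
        "vfarch_version": __version__,
        "seed": seed,
        "params": params,
        "inputs": inputs,
        "outputs": outputs,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
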