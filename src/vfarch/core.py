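"""24-2 visual-field grid geometry and binocular integration.

Coordinates are visual-field degrees shared by both eyes: negative ``x`` is
the left visual field, positive ``y`` is superior.  Each eye tests 54
locations; the two layouts differ only in the single nasal-extension point
per ``y = ±3`` row (``x = -27`` for the right eye, ``x = +27`` for the
left).  The 52 locations common to both eyes (all ``|x| <= 21``) form the
binocular grid.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

RIGHT = "right"
LEFT = "left"

_EYE_ALIASES = {
    "right": RIGHT, "od": RIGHT, "r": RIGHT, "re": RIGHT,
    "left": LEFT, "os": LEFT, "l": LEFT, "le": LEFT,
}

#: Upper bound for a monocular sensitivity in dB.
MAX_DB = 50.0
#: Upper bound for a binocular (quadratically summed) sensitivity in dB.
BINOC_MAX_DB = math.sqrt(2.0) * MAX_DB

_SQRT2 = math.sqrt(2.0)

# x offsets per |y| row for the 24-2 layout (nasal extension handled apart)
_ROW_X = {
    21: (-9, -3, 3, 9),
    15: (-15, -9, -3, 3, 9, 15),
    9: (-21, -15, -9, -3, 3, 9, 15, 21),
    3: (-21, -15, -9, -3, 3, 9, 15, 21),
}
_ROW_ORDER = (21, 15, 9, 3, -3, -9, -15, -21)


def normalize_eye(eye: str) -> str:
    """Map an eye label (``right``/``left``/``OD``/``OS``…) to canonical form."""
    try:
        return _EYE_ALIASES[str(eye).strip().lower()]
    except KeyError:
        raise ValueError(f"unknown laterality: {eye!r}") from None


@dataclass(frozen=True, order=True)
class GridLocation:
    """A single test location in visual-field degrees."""

    x: int
    y: int

    @property
    def name(self) -> str:
        return f"x{self.x:+d}y{self.y:+d}"

    @classmethod
    def from_name(cls, name: str) -> "GridLocation":
        if not name.startswith("x") or "y" not in name:
            raise ValueError(f"bad location name: {name!r}")
        xs, ys = name[1:].split("y")
        return cls(int(xs), int(ys))


def grid_24_2(eye: str) -> tuple[GridLocation, ...]:
    """Canonically ordered 24-2 layout for one eye.

    Ordering is row-major: ``y`` descending, then ``x`` ascending.  Exactly
    54 locations, including one nasal-extension point per ``y = ±3`` row.
    """
    eye = normalize_eye(eye)
    nasal_x = -27 if eye == RIGHT else 27
    locs: list[GridLocation] = []
    for y in _ROW_ORDER:
        xs = list(_ROW_X[abs(y)])
        if abs(y) == 3:
            xs.append(nasal_x)
        for x in sorted(xs):
            locs.append(GridLocation(x, y))
    return tuple(locs)


def shared_grid() -> tuple[GridLocation, ...]:
    """The 52 locations common to both eyes (``|x| <= 21``), canonical order."""
    return tuple(loc for loc in grid_24_2(RIGHT) if abs(loc.x) <= 21)


#: Physiological blind-spot locations per eye.
BLIND_SPOTS = {
    RIGHT: (GridLocation(15, 3), GridLocation(15, -3)),
    LEFT: (GridLocation(-15, 3), GridLocation(-15, -3)),
}

_GRID_SETS = {RIGHT: frozenset(grid_24_2(RIGHT)), LEFT: frozenset(grid_24_2(LEFT))}
SHARED_GRID = shared_grid()
SHARED_NAMES = tuple(loc.name for loc in SHARED_GRID)


def _check_rate(value: float | None, label: str) -> float | None:
    if value is None:
        return None
    value = float(value)
    if math.isnan(value):
        return None
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{label} outside [0, 1]: {value}")
    return value


@dataclass(frozen=True)
class MonocularVF:
    """One eye's 24-2 test: 54 located sensitivities plus reliability metadata."""

    patient_id: str
    eye: str
    test_date: _dt.date
    sensitivities: Mapping[GridLocation, float]
    foveal_db: float | None = None
    fp_rate: float | None = None
    fn_rate: float | None = None
    fl_rate: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "eye", normalize_eye(self.eye))
        expected = _GRID_SETS[self.eye]
        sens = {k: float(v) for k, v in self.sensitivities.items()}
        got = frozenset(sens)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            parts = []
            if missing:
                parts.append("missing " + ", ".join(l.name for l in missing))
            if extra:
                parts.append("extra " + ", ".join(l.name for l in extra))
            raise ValueError(
                f"{self.patient_id}/{self.eye}: invalid 24-2 grid ({'; '.join(parts)})"
            )
        for loc, v in sens.items():
            if not math.isfinite(v) or not 0.0 <= v <= MAX_DB:
                raise ValueError(
                    f"{self.patient_id}/{self.eye}: sensitivity at {loc.name} "
                    f"outside [0, {MAX_DB:g}] dB: {v}"
                )
        object.__setattr__(self, "sensitivities", sens)
        if self.foveal_db is not None:
            f = float(self.foveal_db)
            if not math.isfinite(f) or not 0.0 <= f <= MAX_DB:
                raise ValueError(f"foveal_db outside [0, {MAX_DB:g}]: {f}")
            object.__setattr__(self, "foveal_db", f)
        object.__setattr__(self, "fp_rate", _check_rate(self.fp_rate, "fp_rate"))
        object.__setattr__(self, "fn_rate", _check_rate(self.fn_rate, "fn_rate"))
        object.__setattr__(self, "fl_rate", _check_rate(self.fl_rate, "fl_rate"))

    def value(self, loc: GridLocation) -> float:
        return self.sensitivities[loc]

    def vector(self) -> np.ndarray:
        """Sensitivities as a length-54 array in canonical grid order."""
        return np.array([self.sensitivities[l] for l in grid_24_2(self.eye)])


@dataclass(frozen=True)
class VFPair:
    """Right/left tests of one patient taken at the same visit."""

    right: MonocularVF
    left: MonocularVF

    def __post_init__(self) -> None:
        if self.right.eye != RIGHT or self.left.eye != LEFT:
            raise ValueError("VFPair requires a right-eye and a left-eye test")
        if self.right.patient_id != self.left.patient_id:
            raise ValueError(
                f"patient mismatch: {self.right.patient_id!r} vs {self.left.patient_id!r}"
            )
        if self.right.test_date != self.left.test_date:
            raise ValueError(
                f"{self.right.patient_id}: tests not from the same visit "
                f"({self.right.test_date} vs {self.left.test_date})"
            )

    @property
    def patient_id(self) -> str:
        return self.right.patient_id

    @property
    def test_date(self) -> _dt.date:
        return self.right.test_date


@dataclass(frozen=True)
class IntegratedVF:
    """Binocular field over the 52 shared locations, with summary values."""

    patient_id: str
    sensitivities: Mapping[GridLocation, float]
    ivf_ms: float
    foveal_binoc_db: float | None = None

    def __post_init__(self) -> None:
        sens = {k: float(v) for k, v in self.sensitivities.items()}
        if frozenset(sens) != frozenset(SHARED_GRID):
            raise ValueError(
                f"{self.patient_id}: integrated field must cover exactly the "
                f"52 shared locations (got {len(sens)})"
            )
        for loc, v in sens.items():
            if not math.isfinite(v) or not 0.0 <= v <= BINOC_MAX_DB + 1e-9:
                raise ValueError(
                    f"{self.patient_id}: binocular value at {loc.name} outside "
                    f"[0, {BINOC_MAX_DB:.3f}]: {v}"
                )
        object.__setattr__(self, "sensitivities", sens)
        mean = sum(sens.values()) / len(sens)
        if abs(mean - float(self.ivf_ms)) > 1e-6:
            raise ValueError(
                f"{self.patient_id}: ivf_ms {self.ivf_ms} does not equal the "
                f"mean of the 52 values ({mean})"
            )

    def vector(self) -> np.ndarray:
        """Binocular sensitivities as a length-52 array in canonical order."""
        return np.array([self.sensitivities[l] for l in SHARED_GRID])

    @classmethod
    def from_vector(
        cls,
        patient_id: str,
        values: Iterable[float],
        foveal_binoc_db: float | None = None,
    ) -> "IntegratedVF":
        vals = np.asarray(list(values), dtype=float)
        if vals.shape != (52,):
            raise ValueError(f"expected 52 values, got {vals.shape}")
        sens = dict(zip(SHARED_GRID, vals))
        return cls(patient_id, sens, float(vals.mean()), foveal_binoc_db)


def binocular_summation(r_db, l_db):
    """Quadratic binocular summation ``sqrt(r**2 + l**2)``.

    Accepts scalars or arrays; inputs must be finite and non-negative
    (negative raw sensitivities are clamped to 0 at import, not here).
    """
    r = np.asarray(r_db, dtype=float)
    l = np.asarray(l_db, dtype=float)
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(l))):
        raise ValueError("binocular_summation requires finite inputs")
    if np.any(r < 0) or np.any(l < 0):
        raise ValueError("binocular_summation requires non-negative inputs")
    out = np.hypot(r, l)
    if out.ndim == 0:
        return float(out)
    return out


def integrate_pair(pair: VFPair) -> IntegratedVF:
    """Integrate a same-visit pair into a 52-location binocular field."""
    sens = {
        loc: binocular_summation(pair.right.value(loc), pair.left.value(loc))
        for loc in SHARED_GRID
    }
    foveal = None
    if pair.right.foveal_db is not None and pair.left.foveal_db is not None:
        foveal = binocular_summation(pair.right.foveal_db, pair.left.foveal_db)
    ivf_ms = sum(sens.values()) / len(sens)
    return IntegratedVF(pair.patient_id, sens, ivf_ms, foveal)
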