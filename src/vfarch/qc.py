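"""Reliability filtering, analysis-visit selection and the homonymous screen."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import SHARED_GRID, GridLocation, MonocularVF, VFPair, grid_24_2

log = logging.getLogger(__name__)

#: Default screen thresholds (documented heuristics, configurable).
DEFAULT_ASYM_THRESHOLD_DB = 5.0
DEFAULT_CORR_THRESHOLD = 0.6

# Reliability cut-offs; all comparisons are strict ("greater than", "exceeding").
FP_LIMIT = 0.10
FN_LIMIT = 0.10
FL_LIMIT = 0.20


def check_reliability(vf: MonocularVF) -> bool:
    """True when the test is reliable.

    A test is unreliable iff false positives exceed 10%, or false negatives
    exceed 10% while fixation losses simultaneously exceed 20%.  Missing
    rates are an error, never silently reliable.
    """
    if vf.fp_rate is None or vf.fn_rate is None or vf.fl_rate is None:
        raise ValueError(
            f"{vf.patient_id}/{vf.eye}/{vf.test_date}: reliability rates missing"
        )
    unreliable = vf.fp_rate > FP_LIMIT or (vf.fn_rate > FN_LIMIT and vf.fl_rate > FL_LIMIT)
    return not unreliable


def pair_is_reliable(pair: VFPair) -> bool:
    """A visit is reliable only if both eyes' tests are reliable."""
    return check_reliability(pair.right) and check_reliability(pair.left)


def select_analysis_visit(pairs: Sequence[VFPair]) -> VFPair | None:
    """Pick the analysis visit for one patient, or None if excluded.

    Patients with fewer than two reliable visits are excluded (learning
    effect); otherwise the most recent reliable visit is used.  Date ties
    are broken by stable input order (first occurrence wins, logged).
    """
    if not pairs:
        log.info("select_analysis_visit: no visits supplied")
        return None
    pid = pairs[0].patient_id
    reliable = [p for p in pairs if pair_is_reliable(p)]
    if len(reliable) < 2:
        log.info("patient %s excluded: %d reliable visit(s)", pid, len(reliable))
        return None
    chosen = reliable[0]
    for p in reliable[1:]:
        if p.test_date > chosen.test_date:
            chosen = p
        elif p.test_date == chosen.test_date:
            log.warning(
                "patient %s: tied visit dates %s; keeping first in input order",
                pid, p.test_date,
            )
    return chosen


def _mirror_pairs(eye: str) -> list[tuple[GridLocation, GridLocation]]:
    locs = frozenset(grid_24_2(eye))
    pairs = []
    for loc in sorted(locs):
        if 0 < loc.x <= 21:
            mirror = GridLocation(-loc.x, loc.y)
            if mirror in locs:
                pairs.append((loc, mirror))
    return pairs


_MIRROR_PAIRS = {eye: _mirror_pairs(eye) for eye in ("right", "left")}


def vertical_midline_asymmetry(vf: MonocularVF) -> float:
    """Mean absolute sensitivity difference across the vertical midline.

    Uses the 26 mirror pairs ``{(x, y), (-x, y)}`` with ``|x| <= 21``; the
    unpaired nasal-extension points cannot enter by construction.
    """
    pairs = _MIRROR_PAIRS[vf.eye]
    diffs = [abs(vf.value(a) - vf.value(b)) for a, b in pairs]
    return float(np.mean(diffs))


def interocular_correlation(pair: VFPair) -> float:
    """Pearson correlation of the two eyes over the 52 shared locations.

    Returns NaN (with a warning) when either eye has zero variance.
    """
    r = np.array([pair.right.value(l) for l in SHARED_GRID])
    l = np.array([pair.left.value(l) for l in SHARED_GRID])
    if np.ptp(r) == 0.0 or np.ptp(l) == 0.0:
        log.warning(
            "patient %s: interocular correlation undefined (zero variance)",
            pair.patient_id,
        )
        return float("nan")
    rc = r - r.mean()
    lc = l - l.mean()
    return float(rc @ lc / math.sqrt((rc @ rc) * (lc @ lc)))


@dataclass(frozen=True)
class NeuroScreenResult:
    """Pair-level statistics of the post-chiasmatic defect screen."""

    vertical_asymmetry_db: float
    interocular_r: float
    flagged: bool

    def __post_init__(self) -> None:
        if self.vertical_asymmetry_db < 0:
            raise ValueError("vertical_asymmetry_db must be >= 0")
        if not math.isnan(self.interocular_r) and not -1.0 <= self.interocular_r <= 1.0:
            raise ValueError("interocular_r outside [-1, 1]")


def neuro_screen(
    pair: VFPair,
    asym_threshold: float = DEFAULT_ASYM_THRESHOLD_DB,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
) -> NeuroScreenResult:
    """Flag pairs with high vertical asymmetry *and* high interocular correlation.

    The pair-level asymmetry is the mean of the two monocular asymmetries.
    A flag marks the record for human review; it does not auto-exclude.
    """
    asym = 0.5 * (
        vertical_midline_asymmetry(pair.right) + vertical_midline_asymmetry(pair.left)
    )
    r = interocular_correlation(pair)
    if math.isnan(r):
        log.warning("patient %s: screen correlation undefined; not flagged", pair.patient_id)
        flagged = False
    else:
        flagged = asym >= asym_threshold and r >= corr_threshold
    return NeuroScreenResult(asym, r, flagged)
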