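"""FNTA-threshold screening of forward head posture (FHP) level.

The forward neck tilt angle (FNTA) — the angle between the vertical and the
tragus–acromion line — is binned into four FHP levels by three cutoffs.
With the default cutoffs (12, 25, 40 degrees) the levels are:

=======  =====================  ==========================
level    FNTA interval (deg)    meaning
=======  =====================  ==========================
0        [0, 12)                Normal
1        [12, 25)               Level 1
2        [25, 40)               Level 2
3        [40, inf)              Level 3 — radiology requested
=======  =====================  ==========================

Every interval is closed on the left and open on the right. The cutoffs are
data, not code: they live in the same constants bank as the boundary lines
(see :mod:`fhpdx.cli_io`) so alternative screening protocols can be
configured without touching this module.
"""

from __future__ import annotations

import math
from typing import Sequence

from .exceptions import ConfigError, DataError

#: Screening cutoffs in degrees: Normal/1, 1/2 and 2/3 boundaries.
DEFAULT_THRESHOLDS: tuple[float, float, float] = (12.0, 25.0, 40.0)

LEVEL_NAMES = {0: "Normal", 1: "Level 1", 2: "Level 2", 3: "Level 3"}


def validate_thresholds(thresholds: Sequence[float]) -> tuple[float, float, float]:
    """Check that *thresholds* is a strictly increasing triple of positive angles."""
    t = tuple(float(v) for v in thresholds)
    if len(t) != 3:
        raise ConfigError(f"expected 3 screening thresholds, got {len(t)}")
    if not all(math.isfinite(v) for v in t):
        raise ConfigError(f"thresholds must be finite, got {t}")
    if not (0 < t[0] < t[1] < t[2]):
        raise ConfigError(f"thresholds must be strictly increasing and positive, got {t}")
    return t


def classify_fnta(
    fnta: float, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> int:
    """Classify an FNTA measurement into an FHP level (0-3).

    Parameters
    ----------
    fnta
        Forward neck tilt angle in degrees; must be >= 0 and finite.
    thresholds
        The three level cutoffs ``(t01, t12, t23)``; each level's interval
        is ``[lower, upper)`` (lower bound inclusive).

    Returns
    -------
    int
        The FHP level: 0 (Normal) through 3 (radiology requested).
    """
    t = validate_thresholds(thresholds)
    fnta = float(fnta)
    if not math.isfinite(fnta) or fnta < 0:
        raise DataError(f"fnta must be finite and >= 0, got {fnta}")
    level = 0
    for cut in t:
        if fnta >= cut:
            level += 1
    return level


def level_interval(
    level: int, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> tuple[float, float]:
    """Return the half-open FNTA interval ``[lower, upper)`` for *level*.

    Level 3 is unbounded above (``upper = inf``).
    """
    t = validate_thresholds(thresholds)
    if level not in (0, 1, 2, 3):
        raise DataError(f"FHP level must be in 0..3, got {level}")
    edges = (0.0, *t, math.inf)
    return edges[level], edges[level + 1]
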