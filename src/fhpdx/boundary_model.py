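"""Linear boundary-line diagnostic models for forward head posture.

Each radiographic parameter gets one diagnostic model: three straight
classification lines in the (parameter, FNTA) plane, each separating a pair
of adjacent FHP levels. A line is stored in the implicit form

    0 = K + L1 * X + L2 * Y

where ``X`` is the radiographic parameter, ``Y`` is the FNTA, and ``L2 < 0``
by convention, so that the boundary FNTA at a given ``X`` is
``Y = -(K + L1 * X) / L2`` and points with larger FNTA lie on the
higher-level side.

Diagnosis uses the FNTA alone: a horizontal line at the measured FNTA is
compared against each boundary's FNTA range over its parameter-axis span.
If the FNTA crosses a boundary within that span, the model cannot decide
between the two levels the boundary separates, and both become candidates.
Eight models vote; the level with the most votes is the diagnosis.

Boundary lines are fitted per adjacent level pair with a two-class Fisher
linear discriminant (equal priors, pooled covariance) on the labelled
training records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import ConfigError, DataError, NumericalError
from .parameters import PARAMETERS
from .screening import DEFAULT_THRESHOLDS, classify_fnta, validate_thresholds
from .synthetic_cohort import ParticipantRecord

#: Conventional names for the three boundary lines, in level order:
#: blue separates Normal/Level 1, pink Level 1/2, red Level 2/3.
LINE_NAMES: tuple[str, str, str] = ("blue", "pink", "red")

ADJACENT_PAIRS: tuple[tuple[int, int], ...] = ((0, 1), (1, 2), (2, 3))


@dataclass(frozen=True)
class BoundaryLine:
    """One classification line ``0 = K + L1*X + L2*Y`` between adjacent levels.

    Attributes
    ----------
    k, l1, l2
        Line constants; ``l2`` is the FNTA coefficient and must be negative.
    x_min, x_max
        The parameter-axis span (left/right endpoints) over which the line
        is defined.
    separates
        The ordered pair of adjacent FHP levels ``(low, high)`` the line
        separates.
    effective_x_min, effective_x_max
        Optional narrower span used for ambiguity determination, e.g. when
        the observed data occupy less than the plotted axis range. Must be
        contained in ``[x_min, x_max]``.
    """

    k: float
    l1: float
    l2: float
    x_min: float
    x_max: float
    separates: tuple[int, int] = (0, 1)
    effective_x_min: float | None = None
    effective_x_max: float | None = None

    def __post_init__(self) -> None:
        for name in ("k", "l1", "l2", "x_min", "x_max"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ConfigError(f"BoundaryLine.{name} must be finite, got {v}")
        if self.l2 == 0:
            raise ConfigError("BoundaryLine.l2 must be nonzero")
        if self.l2 > 0:
            # normalise to the l2 < 0 sign convention
            object.__setattr__(self, "k", -self.k)
            object.__setattr__(self, "l1", -self.l1)
            object.__setattr__(self, "l2", -self.l2)
        if not self.x_min < self.x_max:
            raise ConfigError(
                f"BoundaryLine requires x_min < x_max, got [{self.x_min}, {self.x_max}]"
            )
        if tuple(self.separates) not in ADJACENT_PAIRS:
            raise ConfigError(
                f"BoundaryLine.separates must be one of {ADJACENT_PAIRS}, "
                f"got {self.separates}"
            )
        lo, hi = self.effective_range
        if not (self.x_min <= lo < hi <= self.x_max):
            raise ConfigError(
                f"effective range [{lo}, {hi}] not contained in "
                f"[{self.x_min}, {self.x_max}]"
            )

    @property
    def effective_range(self) -> tuple[float, float]:
        lo = self.x_min if self.effective_x_min is None else self.effective_x_min
        hi = self.x_max if self.effective_x_max is None else self.effective_x_max
        return lo, hi

    def fnta_at(self, x: float) -> float:
        return boundary_fnta_at(self, x)

    def fnta_range(self) -> tuple[float, float]:
        return boundary_fnta_range(self)


def boundary_fnta_at(line: BoundaryLine, x: float) -> float:
    """Boundary FNTA at parameter value *x*: ``-(K + L1*x) / L2``.

    *x* must lie within the line's ``[x_min, x_max]`` span.
    """
    if not (line.x_min <= x <= line.x_max):
        raise DataError(
            f"x={x} outside the line's range [{line.x_min}, {line.x_max}]"
        )
    return -(line.k + line.l1 * x) / line.l2


def boundary_fnta_range(line: BoundaryLine) -> tuple[float, float]:
    """(min, max) of the boundary FNTA over the line's effective span.

    The boundary is affine in ``x``, so its extrema over an interval are
    attained at the endpoints.
    """
    lo, hi = line.effective_range
    y_lo = boundary_fnta_at(line, lo)
    y_hi = boundary_fnta_at(line, hi)
    return (y_lo, y_hi) if y_lo <= y_hi else (y_hi, y_lo)


@dataclass(frozen=True)
class DiagnosticModel:
    """Three ordered boundary lines for one radiographic parameter."""

    parameter: str
    lines: tuple[BoundaryLine, BoundaryLine, BoundaryLine]

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ConfigError(
                f"unknown parameter {self.parameter!r}; expected one of {PARAMETERS}"
            )
        if len(self.lines) != 3:
            raise ConfigError(f"DiagnosticModel needs 3 lines, got {len(self.lines)}")
        object.__setattr__(self, "lines", tuple(self.lines))
        for line, pair in zip(self.lines, ADJACENT_PAIRS):
            if tuple(line.separates) != pair:
                raise ConfigError(
                    f"lines must separate {ADJACENT_PAIRS} in order; "
                    f"got {line.separates} where {pair} expected"
                )
        # ordering invariant: at the midpoint of the common x-span the
        # boundaries must be stacked blue < pink < red
        lo = max(l.x_min for l in self.lines)
        hi = min(l.x_max for l in self.lines)
        if not lo < hi:
            raise ConfigError("lines have no common x-range")
        mid = 0.5 * (lo + hi)
        y = [boundary_fnta_at(l, mid) for l in self.lines]
        if not (y[0] < y[1] < y[2]):
            raise NumericalError(
                f"boundary ordering violated for {self.parameter}: FNTA at "
                f"x={mid:.3g} is {y[0]:.3f}, {y[1]:.3f}, {y[2]:.3f} "
                "(expected blue < pink < red)"
            )


@dataclass(frozen=True)
class ModelBank:
    """Eight diagnostic models (one per parameter) plus the screening cutoffs."""

    models: Mapping[str, DiagnosticModel]
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        object.__setattr__(self, "models", dict(self.models))
        object.__setattr__(
            self, "thresholds", validate_thresholds(self.thresholds)
        )
        missing = [p for p in PARAMETERS if p not in self.models]
        extra = [p for p in self.models if p not in PARAMETERS]
        if missing or extra:
            raise ConfigError(
                f"ModelBank must hold exactly one model per parameter "
                f"{PARAMETERS}; missing={missing}, unexpected={extra}"
            )
        for p, m in self.models.items():
            if m.parameter != p:
                raise ConfigError(
                    f"model under key {p!r} is for parameter {m.parameter!r}"
                )

    def __getitem__(self, parameter: str) -> DiagnosticModel:
        return self.models[parameter]


@dataclass(frozen=True)
class CandidateSet:
    """A nonempty contiguous run of FHP levels a model cannot tell apart."""

    levels: frozenset[int]

    def __post_init__(self) -> None:
        levels = frozenset(int(l) for l in self.levels)
        object.__setattr__(self, "levels", levels)
        if not levels:
            raise DataError("CandidateSet must be nonempty")
        if not levels <= {0, 1, 2, 3}:
            raise DataError(f"levels must be within 0..3, got {sorted(levels)}")
        lo, hi = min(levels), max(levels)
        if levels != frozenset(range(lo, hi + 1)):
            raise DataError(f"levels must be contiguous, got {sorted(levels)}")

    def __contains__(self, level: int) -> bool:
        return level in self.levels

    def __len__(self) -> int:
        return len(self.levels)

    def __iter__(self):
        return iter(sorted(self.levels))

    def notation(self) -> str:
        """Dotted notation used in diagnosis sheets, e.g. ``"0.1"`` for {0, 1}."""
        return ".".join(str(l) for l in sorted(self.levels))

    @classmethod
    def from_notation(cls, text: str) -> "CandidateSet":
        try:
            levels = frozenset(int(tok) for tok in str(text).strip().split("."))
        except ValueError as exc:
            raise DataError(f"cannot parse candidate notation {text!r}") from exc
        return cls(levels)


@dataclass(frozen=True)
class DiagnosisResult:
    """Outcome of the eight-model vote for one FNTA measurement."""

    fnta: float
    per_model_candidates: Mapping[str, CandidateSet]
    vote_counts: tuple[int, int, int, int]
    pc_level: int
    final_level: int
    tie_flag: bool = False
    participant_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "per_model_candidates", dict(self.per_model_candidates)
        )
        total = sum(len(c) for c in self.per_model_candidates.values())
        if total != sum(self.vote_counts):
            raise DataError(
                "vote counts inconsistent with candidate sets: "
                f"{self.vote_counts} vs {total} candidate memberships"
            )
        if self.vote_counts[self.final_level] != max(self.vote_counts):
            raise DataError("final_level does not attain the maximum vote count")


def _boundary_state(line: BoundaryLine, fnta: float) -> int:
    """-1 below, 0 ambiguous, +1 above, relative to the boundary's FNTA range.

    An FNTA exactly equal to the range minimum counts as below (the lower
    level is unambiguous); exactly equal to the maximum counts as above.
    """
    y_min, y_max = boundary_fnta_range(line)
    if fnta <= y_min:
        return -1
    if fnta >= y_max:
        return 1
    return 0


def candidate_levels(model: DiagnosticModel, fnta: float) -> CandidateSet:
    """Candidate FHP levels for *fnta* under one diagnostic model.

    Level ``l`` is a candidate iff every boundary below it (separating
    levels ``< l`` from the next) is above-or-ambiguous and every boundary
    at or above it is below-or-ambiguous. The result is nonempty and
    contiguous because boundary states are monotone in the boundary index.
    """
    if not math.isfinite(fnta) or fnta < 0:
        raise DataError(f"fnta must be finite and >= 0, got {fnta}")
    states = [_boundary_state(line, fnta) for line in model.lines]
    levels = {
        l
        for l in range(4)
        if all(states[i] >= 0 for i in range(l)) and all(states[i] <= 0 for i in range(l, 3))
    }
    if not levels:
        # boundary ranges overlap at this fnta (crossed lines); fall back to
        # the widest consistent run between the outermost ambiguous bounds
        raise NumericalError(
            f"no consistent level for fnta={fnta} under model "
            f"{model.parameter}: boundary states {states}"
        )
    return CandidateSet(frozenset(levels))


def vote_diagnosis(
    bank: ModelBank, fnta: float, participant_id: str | None = None
) -> DiagnosisResult:
    """Majority-vote diagnosis of one FNTA across the bank's eight models.

    Each model casts one vote for every level in its candidate set. The
    diagnosis is the level with the most votes; on a tie the highest tied
    level wins (conservative toward radiographic referral) and ``tie_flag``
    is set. ``pc_level`` is the plain threshold classification.
    """
    per_model = {p: candidate_levels(bank[p], fnta) for p in PARAMETERS}
    counts = [0, 0, 0, 0]
    for cset in per_model.values():
        for level in cset:
            counts[level] += 1
    best = max(counts)
    winners = [l for l in range(4) if counts[l] == best]
    return DiagnosisResult(
        fnta=float(fnta),
        per_model_candidates=per_model,
        vote_counts=tuple(counts),
        pc_level=classify_fnta(fnta, bank.thresholds),
        final_level=winners[-1],
        tie_flag=len(winners) > 1,
        participant_id=participant_id,
    )


def diagnose_cohort(
    bank: ModelBank,
    fntas: Sequence[float],
    participant_ids: Sequence[str] | None = None,
) -> list[DiagnosisResult]:
    """Vote-diagnose a sequence of FNTA measurements."""
    if participant_ids is None:
        participant_ids = [str(i + 1) for i in range(len(fntas))]
    if len(participant_ids) != len(fntas):
        raise DataError("participant_ids and fntas must have equal length")
    return [
        vote_diagnosis(bank, f, pid) for f, pid in zip(fntas, participant_ids)
    ]


# ---------------------------------------------------------------------------
# fitting


def fit_boundary(
    points_low: Sequence[tuple[float, float]],
    points_high: Sequence[tuple[float, float]],
    separates: tuple[int, int] = (0, 1),
) -> BoundaryLine:
    """Fit the linear boundary between two groups of (x, fnta) points.

    Two-class Fisher linear discriminant with equal priors and pooled
    covariance: the boundary is the locus of equal discriminant scores,

        w = S_pooled^{-1} (mu_high - mu_low),   w . (z - (mu_low+mu_high)/2) = 0,

    expressed as ``0 = K + L1*x + L2*y`` and sign-normalised to ``L2 < 0``.
    The x-span is the observed x-range of the pooled points.
    """
    a = np.asarray(points_low, dtype=float)
    b = np.asarray(points_high, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or b.ndim != 2 or b.shape[1] != 2:
        raise DataError("points must be sequences of (x, fnta) pairs")
    if len(a) < 2 or len(b) < 2:
        raise DataError(
            f"need >= 2 points per group, got {len(a)} and {len(b)}"
        )
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    pooled = (
        (a - mu_a).T @ (a - mu_a) + (b - mu_b).T @ (b - mu_b)
    ) / (len(a) + len(b) - 2)
    try:
        w = np.linalg.solve(pooled, mu_b - mu_a)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"degenerate fit: pooled covariance singular ({exc})")
    if not np.all(np.isfinite(w)) or np.allclose(w, 0):
        raise NumericalError("degenerate fit: coincident group means")
    mid = 0.5 * (mu_a + mu_b)
    k = -float(w @ mid)
    l1, l2 = float(w[0]), float(w[1])
    if l2 == 0:
        raise NumericalError(
            "degenerate fit: boundary is vertical in the (x, fnta) plane"
        )
    xs = np.concatenate([a[:, 0], b[:, 0]])
    x_min, x_max = float(xs.min()), float(xs.max())
    if not x_min < x_max:
        raise NumericalError("degenerate fit: all points share one x value")
    return BoundaryLine(
        k=k, l1=l1, l2=l2, x_min=x_min, x_max=x_max, separates=tuple(separates)
    )


def fit_diagnostic_model(
    train: Iterable[ParticipantRecord], parameter: str
) -> DiagnosticModel:
    """Fit one parameter's three-boundary model from labelled records.

    Records must carry ``known_level`` covering all four levels; each
    boundary is fitted on the two adjacent levels it separates. A violated
    blue < pink < red ordering raises :class:`NumericalError` rather than
    being silently reordered.
    """
    if parameter not in PARAMETERS:
        raise ConfigError(f"unknown parameter {parameter!r}")
    by_level: dict[int, list[tuple[float, float]]] = {0: [], 1: [], 2: [], 3: []}
    for rec in train:
        if rec.known_level is None:
            raise DataError(
                f"record {rec.participant_id!r} lacks known_level; "
                "fit requires labelled records"
            )
        by_level[rec.known_level].append((rec.params[parameter], rec.fnta))
    for level, pts in by_level.items():
        if len(pts) < 2:
            raise DataError(
                f"level {level} has {len(pts)} record(s); need >= 2 to fit"
            )
    lines = tuple(
        fit_boundary(by_level[lo], by_level[hi], separates=(lo, hi))
        for lo, hi in ADJACENT_PAIRS
    )
    # give all three lines the common pooled x-span so the model's lines are
    # comparable over one axis, as on a shared scatter plot
    x_min = min(l.x_min for l in lines)
    x_max = max(l.x_max for l in lines)
    lines = tuple(replace(l, x_min=x_min, x_max=x_max) for l in lines)
    return DiagnosticModel(parameter=parameter, lines=lines)


def fit_model_bank(
    train: Iterable[ParticipantRecord],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> ModelBank:
    """Fit the full eight-model bank from labelled training records."""
    records = list(train)
    return ModelBank(
        models={p: fit_diagnostic_model(records, p) for p in PARAMETERS},
        thresholds=tuple(thresholds),
    )
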