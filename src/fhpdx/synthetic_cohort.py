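"""Seeded synthetic cohorts with per-level distributional structure.

Real screening cohorts for forward head posture pair an externally measured
forward neck tilt angle (FNTA) with eight radiographic sagittal-alignment
parameters per participant. This module generates synthetic stand-ins with
the same shape: within each FHP level, FNTA and every parameter are normal
with configurable means and SDs, FNTA optionally truncated to the level's
screening interval so the generating level agrees with the threshold
classification, and an optional per-parameter FNTA correlation imposed
through a Gaussian-copula construction (a shared latent standard normal).

The packaged default specification carries the published per-level means
and SDs; per-level counts default to (38, 55, 36, 16), a documented
placeholder summing to the study's 145 participants.

Everything is driven by one `numpy.random.Generator` seeded from the spec,
so a spec (including its seed) identifies a cohort exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

from .exceptions import ConfigError, DataError
from .parameters import PARAMETERS
from .screening import DEFAULT_THRESHOLDS, classify_fnta, level_interval

_PARAM_SET = frozenset(PARAMETERS)


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant: FNTA plus the eight radiographic parameters."""

    participant_id: str
    fnta: float
    params: Mapping[str, float]
    known_level: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.fnta):
            raise DataError(
                f"participant {self.participant_id!r}: fnta must be finite"
            )
        params = dict(self.params)
        object.__setattr__(self, "params", params)
        if set(params) != _PARAM_SET:
            raise DataError(
                f"participant {self.participant_id!r}: params keys must be "
                f"exactly {sorted(_PARAM_SET)}, got {sorted(params)}"
            )
        if not all(math.isfinite(v) for v in params.values()):
            raise DataError(
                f"participant {self.participant_id!r}: non-finite parameter value"
            )
        if self.known_level is not None and self.known_level not in (0, 1, 2, 3):
            raise DataError(
                f"participant {self.participant_id!r}: known_level must be 0-3"
            )


@dataclass(frozen=True)
class LevelDistribution:
    """Normal distribution parameters for one FHP level."""

    level: int
    fnta_mean: float
    fnta_sd: float
    param_means: Mapping[str, float]
    param_sds: Mapping[str, float]
    n: int

    def __post_init__(self) -> None:
        if self.level not in (0, 1, 2, 3):
            raise ConfigError(f"level must be 0-3, got {self.level}")
        if self.fnta_sd < 0:
            raise ConfigError(f"level {self.level}: fnta_sd must be >= 0")
        if self.n < 0:
            raise ConfigError(f"level {self.level}: n must be >= 0")
        object.__setattr__(self, "param_means", dict(self.param_means))
        object.__setattr__(self, "param_sds", dict(self.param_sds))
        for name, mapping in (("param_means", self.param_means),
                              ("param_sds", self.param_sds)):
            if set(mapping) != _PARAM_SET:
                raise ConfigError(
                    f"level {self.level}: {name} keys must be exactly "
                    f"{sorted(_PARAM_SET)}, got {sorted(mapping)}"
                )
        if any(sd < 0 for sd in self.param_sds.values()):
            raise ConfigError(f"level {self.level}: param_sds must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort (four levels plus options)."""

    levels: tuple[LevelDistribution, ...]
    seed: int = 0
    truncate_fnta_to_level_range: bool = True
    correlation_fnta_param: Mapping[str, float] | None = None
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        levels = tuple(self.levels)
        object.__setattr__(self, "levels", levels)
        if sorted(d.level for d in levels) != [0, 1, 2, 3]:
            raise ConfigError(
                "CohortSpec needs exactly four LevelDistribution entries, "
                f"levels 0..3 each once; got levels {[d.level for d in levels]}"
            )
        if self.correlation_fnta_param is not None:
            corr = dict(self.correlation_fnta_param)
            object.__setattr__(self, "correlation_fnta_param", corr)
            unknown = set(corr) - _PARAM_SET
            if unknown:
                raise ConfigError(f"correlation for unknown parameters {sorted(unknown)}")
            bad = {k: v for k, v in corr.items() if not -1.0 <= v <= 1.0}
            if bad:
                raise ConfigError(f"correlations must lie in [-1, 1], got {bad}")

    def total_n(self) -> int:
        return sum(d.n for d in self.levels)


def default_spec(seed: int | None = None) -> CohortSpec:
    """The packaged default cohort specification (published per-level moments)."""
    text = resources.files("fhpdx.data").joinpath("cohort_spec.yaml").read_text()
    spec = spec_from_dict(yaml.safe_load(text))
    if seed is not None:
        spec = CohortSpec(
            levels=spec.levels,
            seed=int(seed),
            truncate_fnta_to_level_range=spec.truncate_fnta_to_level_range,
            correlation_fnta_param=spec.correlation_fnta_param,
            thresholds=spec.thresholds,
        )
    return spec


def spec_from_dict(cfg: Mapping) -> CohortSpec:
    """Build a :class:`CohortSpec` from a parsed configuration mapping."""
    try:
        levels = tuple(
            LevelDistribution(
                level=int(entry["level"]),
                fnta_mean=float(entry["fnta"]["mean"]),
                fnta_sd=float(entry["fnta"]["sd"]),
                param_means={k: float(v["mean"]) for k, v in entry["params"].items()},
                param_sds={k: float(v["sd"]) for k, v in entry["params"].items()},
                n=int(entry["n"]),
            )
            for entry in cfg["levels"]
        )
    except KeyError as exc:
        raise ConfigError(f"cohort spec missing field {exc}") from exc
    return CohortSpec(
        levels=levels,
        seed=int(cfg.get("seed", 0)),
        truncate_fnta_to_level_range=bool(
            cfg.get("truncate_fnta_to_level_range", True)
        ),
        correlation_fnta_param=cfg.get("correlation_fnta_param"),
        thresholds=tuple(cfg.get("thresholds", DEFAULT_THRESHOLDS)),
    )


def _draw_fnta(
    z: np.ndarray, dist: LevelDistribution, spec: CohortSpec
) -> np.ndarray:
    """Map latent standard normals to FNTA values for one level."""
    mu, sd = dist.fnta_mean, dist.fnta_sd
    if not spec.truncate_fnta_to_level_range:
        return mu + sd * z
    lo, hi = level_interval(dist.level, spec.thresholds)
    if sd == 0:
        if not lo <= mu < hi:
            raise ConfigError(
                f"level {dist.level}: fnta mean {mu} outside its interval "
                f"[{lo}, {hi}) with sd=0"
            )
        return np.full(z.shape, mu)
    a, b = (lo - mu) / sd, (hi - mu) / sd
    # copula transform: latent z -> uniform -> truncated-normal quantile,
    # monotone in z so imposed correlations carry through
    return stats.truncnorm.ppf(stats.norm.cdf(z), a, b, loc=mu, scale=sd)


def generate_cohort(spec: CohortSpec) -> list[ParticipantRecord]:
    """Generate a seeded synthetic cohort from *spec*.

    Returns one record per participant, levels in ascending order,
    ``known_level`` set to the generating level. Identical spec (including
    seed) yields an identical cohort.
    """
    rng = np.random.default_rng(spec.seed)
    corr = dict(spec.correlation_fnta_param or {})
    records: list[ParticipantRecord] = []
    counter = 0
    for dist in sorted(spec.levels, key=lambda d: d.level):
        n = dist.n
        z = rng.standard_normal(n)
        fnta = _draw_fnta(z, dist, spec)
        values = {}
        for name in PARAMETERS:
            r = float(corr.get(name, 0.0))
            eps = rng.standard_normal(n)
            latent = r * z + math.sqrt(1.0 - r * r) * eps
            values[name] = dist.param_means[name] + dist.param_sds[name] * latent
        for i in range(n):
            counter += 1
            records.append(
                ParticipantRecord(
                    participant_id=f"P{counter:04d}",
                    fnta=float(fnta[i]),
                    params={name: float(values[name][i]) for name in PARAMETERS},
                    known_level=dist.level,
                )
            )
    return records


def split_cohort(
    records: Sequence[ParticipantRecord],
    train_fraction: float = 0.70,
    stratify: bool = True,
    seed: int = 0,
) -> tuple[list[ParticipantRecord], list[ParticipantRecord]]:
    """Split a cohort into (train, eval) lists.

    The evaluation set holds ``floor((1 - train_fraction) * n)`` records;
    with ``stratify=True`` the evaluation counts per FHP level are
    proportional to level sizes (largest-remainder rounding), emulating a
    level-balanced random split. The partition is disjoint, exhaustive and
    seeded; both halves keep the input record order.
    """
    if not records:
        raise DataError("cannot split an empty cohort")
    if not 0.0 < train_fraction < 1.0:
        raise ConfigError(
            f"train_fraction must be in (0, 1), got {train_fraction}"
        )
    n = len(records)
    n_eval = int(math.floor((1.0 - train_fraction) * n))
    rng = np.random.default_rng(seed)
    if not stratify:
        perm = rng.permutation(n)
        eval_idx = set(perm[:n_eval].tolist())
    else:
        by_level: dict[int, list[int]] = {}
        for i, rec in enumerate(records):
            lvl = (
                rec.known_level
                if rec.known_level is not None
                else classify_fnta(rec.fnta)
            )
            by_level.setdefault(lvl, []).append(i)
        quotas = {lvl: n_eval * len(idx) / n for lvl, idx in by_level.items()}
        base = {lvl: int(math.floor(q)) for lvl, q in quotas.items()}
        leftover = n_eval - sum(base.values())
        by_frac = sorted(
            by_level, key=lambda lvl: (-(quotas[lvl] - base[lvl]), lvl)
        )
        for lvl in by_frac[:leftover]:
            base[lvl] += 1
        eval_idx = set()
        for lvl in sorted(by_level):
            idx = np.asarray(by_level[lvl])
            take = rng.permutation(len(idx))[: base[lvl]]
            eval_idx.update(idx[take].tolist())
    train = [rec for i, rec in enumerate(records) if i not in eval_idx]
    ev = [rec for i, rec in enumerate(records) if i in eval_idx]
    return train, ev
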