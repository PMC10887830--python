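"""Agreement, confusion and correlation reporting for the FHP pipeline.

Evaluates the voted diagnosis (D) against the FNTA-threshold classification
(PC) — percent agreement plus a 4x4 confusion chart with per-row
true-positive / false-negative rates and per-column positive predictive
value / false discovery rate — and reproduces the structure of the study's
statistical tables: Shapiro-Wilk normality per parameter, Spearman and
Pearson correlations of each parameter against FNTA and against the FHP
level treated as an integer score, and per-level summary moments.

Rates on empty confusion rows or columns are undefined and reported as
missing (NaN), never as zero. Sample SDs use the n-1 denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError
from .parameters import PARAMETERS
from .screening import classify_fnta
from .synthetic_cohort import ParticipantRecord

LEVELS = (0, 1, 2, 3)


def _check_levels(name: str, values: Sequence[int]) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size == 0:
        raise DataError(f"{name} must be nonempty")
    if not np.isin(arr, LEVELS).all():
        raise DataError(f"{name} contains levels outside 0..3")
    return arr.astype(int)


def agreement_ratio(pc: Sequence[int], d: Sequence[int]) -> float:
    """Percent agreement between two level sequences, to two decimals."""
    a = _check_levels("pc", pc)
    b = _check_levels("d", d)
    if len(a) != len(b):
        raise DataError(f"length mismatch: {len(a)} vs {len(b)}")
    return round(100.0 * float((a == b).mean()), 2)


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion chart of threshold classification (rows) vs diagnosis (columns)."""

    n: int
    agreement_ratio: float
    confusion: np.ndarray  # 4x4 counts, rows = PC, columns = D
    row_rates: Mapping[int, dict]  # level -> {"tpr": %, "fnr": %} or None if empty
    col_rates: Mapping[int, dict]  # level -> {"ppv": %, "fdr": %} or None if empty
    disagreements: tuple  # (participant_id, pc, d) triples

    def to_frame(self) -> pd.DataFrame:
        """Counts as a labelled DataFrame (rows PC, columns D)."""
        return pd.DataFrame(
            self.confusion,
            index=pd.Index(LEVELS, name="PC"),
            columns=pd.Index(LEVELS, name="D"),
        )


def confusion_report(
    pc: Sequence[int],
    d: Sequence[int],
    participant_ids: Sequence[str] | None = None,
) -> EvaluationReport:
    """Build the 4x4 confusion chart with row and column rate margins."""
    a = _check_levels("pc", pc)
    b = _check_levels("d", d)
    if len(a) != len(b):
        raise DataError(f"length mismatch: {len(a)} vs {len(b)}")
    if participant_ids is None:
        participant_ids = [str(i + 1) for i in range(len(a))]
    conf = np.zeros((4, 4), dtype=int)
    np.add.at(conf, (a, b), 1)
    row_rates = {}
    for lvl in LEVELS:
        total = conf[lvl].sum()
        if total == 0:
            row_rates[lvl] = None
        else:
            tpr = 100.0 * conf[lvl, lvl] / total
            row_rates[lvl] = {"tpr": tpr, "fnr": 100.0 - tpr}
    col_rates = {}
    for lvl in LEVELS:
        total = conf[:, lvl].sum()
        if total == 0:
            col_rates[lvl] = None
        else:
            ppv = 100.0 * conf[lvl, lvl] / total
            col_rates[lvl] = {"ppv": ppv, "fdr": 100.0 - ppv}
    disagreements = tuple(
        (pid, int(x), int(y))
        for pid, x, y in zip(participant_ids, a, b)
        if x != y
    )
    return EvaluationReport(
        n=len(a),
        agreement_ratio=agreement_ratio(a, b),
        confusion=conf,
        row_rates=row_rates,
        col_rates=col_rates,
        disagreements=disagreements,
    )


@dataclass(frozen=True)
class CorrelationRow:
    """Normality and correlation statistics for one radiographic parameter."""

    parameter: str
    normality_p: float
    spearman_rho_fnta: float
    spearman_p_fnta: float
    pearson_r_fnta: float
    pearson_p_fnta: float
    spearman_rho_level: float
    spearman_p_level: float
    pearson_r_level: float
    pearson_p_level: float
    constant: bool = False


def correlation_table(
    cohort: Sequence[ParticipantRecord],
    exact_below: int = 20,
    seed: int = 0,
) -> list[CorrelationRow]:
    """Per-parameter normality and correlation statistics against FNTA and level.

    Shapiro-Wilk tests each parameter's marginal normality; Spearman's rho
    (average ranks for ties) and Pearson's r are computed against FNTA and
    against the FHP level as an integer 0-3 score, with two-sided p-values.
    For cohorts smaller than *exact_below* the p-values use an exact
    permutation distribution instead of the t approximation. A
    constant-valued parameter yields a flagged row with NaN statistics.
    """
    if len(cohort) < 4:
        raise DataError(f"need >= 4 records, got {len(cohort)}")
    fnta = np.array([r.fnta for r in cohort], dtype=float)
    levels = np.array(
        [
            r.known_level if r.known_level is not None else classify_fnta(r.fnta)
            for r in cohort
        ],
        dtype=float,
    )
    n = len(cohort)
    method = None
    if n < exact_below:
        method = stats.PermutationMethod(
            n_resamples=9999, rng=np.random.default_rng(seed)
        )
    rows = []
    for name in PARAMETERS:
        x = np.array([r.params[name] for r in cohort], dtype=float)
        if np.ptp(x) == 0:
            rows.append(
                CorrelationRow(
                    parameter=name,
                    normality_p=math.nan,
                    spearman_rho_fnta=math.nan, spearman_p_fnta=math.nan,
                    pearson_r_fnta=math.nan, pearson_p_fnta=math.nan,
                    spearman_rho_level=math.nan, spearman_p_level=math.nan,
                    pearson_r_level=math.nan, pearson_p_level=math.nan,
                    constant=True,
                )
            )
            continue
        sw = stats.shapiro(x)
        kw = {"method": method} if method is not None else {}
        s_f = stats.spearmanr(x, fnta)
        p_f = stats.pearsonr(x, fnta, **kw)
        s_l = stats.spearmanr(x, levels)
        p_l = stats.pearsonr(x, levels, **kw)
        rows.append(
            CorrelationRow(
                parameter=name,
                normality_p=float(sw.pvalue),
                spearman_rho_fnta=float(s_f.statistic),
                spearman_p_fnta=float(s_f.pvalue),
                pearson_r_fnta=float(p_f.statistic),
                pearson_p_fnta=float(p_f.pvalue),
                spearman_rho_level=float(s_l.statistic),
                spearman_p_level=float(s_l.pvalue),
                pearson_r_level=float(p_l.statistic),
                pearson_p_level=float(p_l.pvalue),
            )
        )
    return rows


def correlation_frame(rows: Sequence[CorrelationRow]) -> pd.DataFrame:
    """Correlation rows as a DataFrame indexed by parameter."""
    return pd.DataFrame([vars(r) for r in rows]).set_index("parameter")


@dataclass(frozen=True)
class LevelSummaryTable:
    """Per-level n, mean and SD for FNTA and every radiographic parameter."""

    table: pd.DataFrame  # index: level 0-3; columns: n, <var>_mean, <var>_sd

    def moments(self, level: int, variable: str) -> tuple[float, float]:
        row = self.table.loc[level]
        return float(row[f"{variable}_mean"]), float(row[f"{variable}_sd"])


def level_summary(cohort: Sequence[ParticipantRecord]) -> LevelSummaryTable:
    """Per-level sample means and SDs (n-1 denominator) of FNTA and parameters.

    Levels come from ``known_level`` when present, otherwise from the
    threshold classification of FNTA. Empty levels appear with n=0 and NaN
    moments; single-record levels have a defined mean but NaN SD.
    """
    if not cohort:
        raise DataError("cohort must be nonempty")
    frame = pd.DataFrame(
        {
            "level": [
                r.known_level if r.known_level is not None else classify_fnta(r.fnta)
                for r in cohort
            ],
            "fnta": [r.fnta for r in cohort],
            **{p: [r.params[p] for r in cohort] for p in PARAMETERS},
        }
    )
    out = pd.DataFrame(index=pd.Index(LEVELS, name="level"))
    grouped = frame.groupby("level")
    out["n"] = grouped.size().reindex(LEVELS, fill_value=0)
    for var in ("fnta", *PARAMETERS):
        out[f"{var}_mean"] = grouped[var].mean().reindex(LEVELS)
        out[f"{var}_sd"] = grouped[var].std(ddof=1).reindex(LEVELS)
    return LevelSummaryTable(table=out)


def plot_confusion(report: EvaluationReport, path: str) -> None:
    """Render the confusion chart with TPR/FNR and PPV/FDR margins to *path*."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6.5, 6))
    conf = report.confusion
    ax.imshow(conf, cmap="Blues", vmin=0, vmax=max(1, conf.max()))
    for i in LEVELS:
        for j in LEVELS:
            ax.text(j, i, str(conf[i, j]), ha="center", va="center",
                    color="black" if conf[i, j] < conf.max() * 0.6 else "white")
    labels = ["Normal", "Level 1", "Level 2", "Level 3"]
    ax.set_xticks(LEVELS, labels)
    ax.set_yticks(LEVELS, labels)
    ax.set_xlabel("Diagnosis (eight-model vote)")
    ax.set_ylabel("FNTA-threshold classification")
    for i in LEVELS:
        rr = report.row_rates[i]
        txt = "-" if rr is None else f"TPR {rr['tpr']:.1f}%\nFNR {rr['fnr']:.1f}%"
        ax.text(3.8, i, txt, va="center", fontsize=8)
    for j in LEVELS:
        cr = report.col_rates[j]
        txt = "-" if cr is None else f"PPV {cr['ppv']:.1f}%\nFDR {cr['fdr']:.1f}%"
        ax.text(j, 3.8, txt, ha="center", fontsize=8)
    ax.set_xlim(-0.5, 4.6)
    ax.set_ylim(4.6, -0.5)
    ax.set_title(f"Agreement {report.agreement_ratio:.2f}% (n={report.n})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
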