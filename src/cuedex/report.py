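"""Paper-style reliability and validity tables.

A reliability table holds eight rows per task — the four outcome measures
(MOT, SR, ME, MV) by the task's two movement directions — each with the
ICC(2,1) and its band, both occasions' means and SDs, SEM, MDC (annotated
with the SD convention used), %MDC with its responsiveness band, and both
candidate p-values (paired t and the ICC F test) side by side: the published
tables caption one p-value column without disambiguating which test produced
it, so both are always emitted.

A validity table holds 16 cells per task: the four session-level measures
(AMO — average movement onset — SR, ME, MV, averaged across directions at
occasion 1) against the four reference assessment scores, as one-tailed
Pearson correlations starred at p <= 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cuedex.metrics import SessionMetrics
from cuedex.psychometrics import (
    ReliabilityResult,
    ValidityResult,
    classify_icc,
    icc_2_1,
    mdc_from_sem,
    paired_t_test,
    pearson_correlation,
    percent_mdc,
    sem_from_sd_icc,
)
from cuedex.session import TASK_DIRECTIONS

__all__ = [
    "METRIC_ORDER", "REFERENCE_SCORES", "ReliabilityTable", "ValidityTable",
    "metrics_long_table", "build_reliability_table", "build_validity_table",
]

logger = logging.getLogger(__name__)

#: Row order of the published reliability tables.
METRIC_ORDER = ("MOT", "SR", "ME", "MV")

#: Reference assessment score columns for convergent validity.
REFERENCE_SCORES = ("PDMS2_GRASP", "PDMS2_VMI", "QUEST_GRASPS", "QUEST_TOTAL")

_LONG_COLUMNS = ["subject_id", "task", "metric", "direction", "occasion", "value"]


def metrics_long_table(session_metrics: list[SessionMetrics]) -> pd.DataFrame:
    """Flatten per-session metric summaries into the tidy long format used by
    the reliability and validity builders:
    (subject_id, task, metric, direction, occasion, value)."""
    rows = []
    for sm in session_metrics:
        for direction, dm in sm.per_direction.items():
            for metric, value in (("MOT", dm.movement_onset_time),
                                  ("SR", dm.success_rate),
                                  ("ME", dm.movement_error),
                                  ("MV", dm.movement_variation)):
                rows.append((sm.subject_id, sm.task_name, metric, direction,
                             sm.occasion, np.nan if value is None else value))
    return pd.DataFrame(rows, columns=_LONG_COLUMNS)


@dataclass
class ReliabilityTable:
    """Eight ReliabilityResult rows for one task, in published row order."""

    task_name: str
    rows: list[ReliabilityResult]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    def to_csv(self, path_or_buf=None):
        return self.to_dataframe().to_csv(path_or_buf, index=False,
                                          float_format="%.6f")

    def to_text(self) -> str:
        """Human-readable layout mirroring the published column headings."""
        lines = [f"Task: {self.task_name}",
                 f"{'Variables':<10}{'ICC':>7}{'Mean (SD) T1':>16}"
                 f"{'Mean (SD) T2':>16}{'MDC':>8}{'%MDC':>8}"
                 f"{'p (t)':>9}{'p (F)':>9}"]
        for r in self.rows:
            pct = f"{r.pct_mdc:.1f}" if r.pct_mdc is not None else "-"
            lines.append(
                f"{r.metric_name + ' (' + r.direction + ')':<10}{r.icc:>7.3f}"
                f"{f'{r.mean1:.2f} ({r.sd1:.2f})':>16}"
                f"{f'{r.mean2:.2f} ({r.sd2:.2f})':>16}"
                f"{r.mdc:>8.2f}{pct:>8}{r.paired_p:>9.4f}{r.icc_p:>9.4f}")
        return "\n".join(lines)


@dataclass
class ValidityTable:
    """16 ValidityResult cells for one task (4 measures x 4 reference scores)."""

    task_name: str
    rows: list[ValidityResult]

    def to_dataframe(self) -> pd.DataFrame:
        recs = [{"cue_metric": r.cue_metric, "reference_score": r.reference_score,
                 "r": r.r, "p_one_tailed": r.p_one_tailed, "n": r.n,
                 "significant": r.significant} for r in self.rows]
        return pd.DataFrame(recs)

    def to_csv(self, path_or_buf=None):
        return self.to_dataframe().to_csv(path_or_buf, index=False,
                                          float_format="%.6f")

    def to_text(self) -> str:
        lines = [f"Task: {self.task_name}",
                 f"{'':<6}" + "".join(f"{s:>22}" for s in REFERENCE_SCORES)]
        metrics = ("AMO", "SR", "ME", "MV")
        by_key = {(r.cue_metric, r.reference_score): r for r in self.rows}
        for m in metrics:
            cells = []
            for s in REFERENCE_SCORES:
                r = by_key[(m, s)]
                star = "*" if r.significant else ""
                cells.append(f"{r.r:+.3f}{star} ({r.p_one_tailed:.3f})")
            lines.append(f"{m:<6}" + "".join(f"{c:>22}" for c in cells))
        return "\n".join(lines)


def _pivot_two_occasions(df: pd.DataFrame, task: str, metric: str,
                         direction: str) -> pd.DataFrame:
    sub = df[(df["task"] == task) & (df["metric"] == metric)
             & (df["direction"] == direction)]
    wide = sub.pivot_table(index="subject_id", columns="occasion",
                           values="value", aggfunc="mean")
    for occ in (1, 2):
        if occ not in wide.columns:
            wide[occ] = np.nan
    wide = wide[[1, 2]]
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        logger.info("%s %s(%s): excluded %d subject(s) missing an occasion",
                    task, metric, direction, dropped)
    return complete


def build_reliability_table(
    metric_long_table: pd.DataFrame,
    task: str,
    *,
    sd_basis: str = "test1",
    confidence: float = 0.90,
) -> ReliabilityTable:
    """Assemble the eight-row test-retest reliability table for one task.

    ``metric_long_table`` is the tidy long format from
    :func:`metrics_long_table`. Subjects missing either occasion for a row are
    excluded from that row (with a logged count). The MDC is built from the
    occasion-1 SD by default (``sd_basis='test2'`` switches), at 90% or 95%
    confidence.
    """
    if sd_basis not in ("test1", "test2"):
        raise ValueError(f"sd_basis must be 'test1' or 'test2', got {sd_basis!r}")
    directions = TASK_DIRECTIONS.get(task)
    if directions is None:
        directions = tuple(metric_long_table.loc[
            metric_long_table["task"] == task, "direction"].unique())

    rows: list[ReliabilityResult] = []
    for metric in METRIC_ORDER:
        for direction in directions:
            wide = _pivot_two_occasions(metric_long_table, task, metric, direction)
            if len(wide) < 2:
                raise ValueError(
                    f"{task} {metric}({direction}): need >= 2 listwise-complete "
                    f"subjects, got {len(wide)}")
            x1 = wide[1].to_numpy()
            x2 = wide[2].to_numpy()
            icc_res = icc_2_1(np.column_stack([x1, x2]))
            icc = icc_res["icc"]
            mean1, sd1 = float(x1.mean()), float(x1.std(ddof=1))
            mean2, sd2 = float(x2.mean()), float(x2.std(ddof=1))
            sem = sem_from_sd_icc(sd1 if sd_basis == "test1" else sd2, icc)
            mdc = mdc_from_sem(sem, confidence)
            if mean1 != 0:
                pct, band = percent_mdc(mdc, mean1)
            else:
                pct, band = None, None
            t_res = paired_t_test(x1, x2)
            rows.append(ReliabilityResult(
                metric_name=metric, direction=direction, icc=icc,
                icc_band=classify_icc(icc), icc_F=icc_res["F"], icc_p=icc_res["p"],
                mean1=mean1, sd1=sd1, mean2=mean2, sd2=sd2, sem=sem, mdc=mdc,
                pct_mdc=pct, pct_mdc_band=band,
                paired_t=t_res["t"], paired_df=int(t_res["df"]), paired_p=t_res["p"],
                n_subjects=len(wide), mdc_sd_basis=sd_basis,
                mdc_confidence=confidence))
    return ReliabilityTable(task_name=task, rows=rows)


def build_validity_table(
    metric_long_table: pd.DataFrame,
    reference_scores: pd.DataFrame,
    task: str,
    *,
    alternative: str = "greater",
) -> ValidityTable:
    """Correlate occasion-1 session measures with reference assessment scores.

    Each CUE measure is collapsed to one value per subject (mean over the two
    directions; SR is likewise the direction mean, which equals the session
    rate under the balanced 15/15 split). ``reference_scores`` needs a
    ``subject_id`` column plus the four score columns. Unmatched subjects are
    dropped with a log line; fewer than 3 matched subjects is an error.
    ``alternative`` sets the one-tailed direction (see
    :func:`cuedex.psychometrics.pearson_correlation`); ``'observed'``
    reproduces the both-signs starring convention of published tables, at the
    cost of a doubled null star rate.
    """
    missing = [c for c in ("subject_id", *REFERENCE_SCORES)
               if c not in reference_scores.columns]
    if missing:
        raise ValueError(f"reference_scores missing columns: {missing}")

    occ1 = metric_long_table[(metric_long_table["task"] == task)
                             & (metric_long_table["occasion"] == 1)]
    per_subject = occ1.pivot_table(index="subject_id", columns="metric",
                                   values="value", aggfunc="mean")
    merged = per_subject.merge(reference_scores.set_index("subject_id"),
                               left_index=True, right_index=True, how="inner")
    dropped = len(per_subject) - len(merged)
    if dropped:
        logger.info("%s validity: dropped %d unmatched subject(s)", task, dropped)
    if len(merged) < 3:
        raise ValueError(
            f"{task} validity: need >= 3 matched subjects, got {len(merged)}")

    rows: list[ValidityResult] = []
    for cue_metric, column in (("AMO", "MOT"), ("SR", "SR"),
                               ("ME", "ME"), ("MV", "MV")):
        for score in REFERENCE_SCORES:
            pair = merged[[column, score]].dropna()
            res = pearson_correlation(pair[column], pair[score], tail="one",
                                      alternative=alternative)
            rows.append(ValidityResult(cue_metric=cue_metric,
                                       reference_score=score,
                                       r=res["r"], p_one_tailed=res["p"],
                                       n=res["n"]))
    return ValidityTable(task_name=task, rows=rows)
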