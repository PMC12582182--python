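"""Validation and clinical-association statistics.

Covers the pipeline-validation and clinical analyses around the MR-free
quantification: intraclass correlation against ground truth, one- and
two-sided Pearson correlations with Bonferroni families, CDR-based clinical
staging, quintile stratification of memory performance, and the longitudinal
baseline-tau-predicts-decline analysis built on the change ratio
``(post - pre) / (pre + 0.1)`` (the 0.1 guards a zero baseline score).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


class DegenerateDataError(ValueError):
    """No variance to apportion (e.g. all ratings identical)."""


# ---------------------------------------------------------------------------
# intraclass correlation


@dataclass
class ICCResult:
    """ICC estimate with a 95% F-distribution confidence interval."""

    icc: float
    ci_low: float
    ci_high: float
    variant: str
    n_subjects: int
    k_raters: int


def icc(truth: Sequence[float], estimate: Sequence[float],
        variant: str = "absolute_agreement") -> ICCResult:
    """Single-measure ICC between paired measurements on the same subjects.

    ``absolute_agreement`` (default) is the two-way mixed/random
    absolute-agreement single-measure coefficient (McGraw & Wong A,1; the
    point estimate coincides with ICC(2,1)), which penalizes systematic
    offsets between methods; ``consistency`` is the two-way mixed
    consistency coefficient (ICC(3,1)), which does not.  Backed by
    ``pingouin.intraclass_corr``; confidence bounds use the F-distribution
    method and are clipped to [-1, 1].
    """
    t = np.asarray(truth, dtype=np.float64)
    e = np.asarray(estimate, dtype=np.float64)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("truth and estimate must be 1D arrays of equal length")
    n = len(t)
    if n < 3:
        raise ValueError("need at least 3 paired measurements")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(e))):
        raise ValueError("non-finite measurements")
    if np.ptp(t) == 0 and np.ptp(e) == 0:
        raise DegenerateDataError("zero total variance: all measurements identical")
    import pingouin as pg

    long = pd.DataFrame({
        "subject": np.tile(np.arange(n), 2),
        "rater": np.repeat(["truth", "estimate"], n),
        "score": np.concatenate([t, e]),
    })
    table = pg.intraclass_corr(long, targets="subject", raters="rater",
                               ratings="score")
    key = {"absolute_agreement": "ICC(A,1)", "consistency": "ICC(C,1)"}.get(variant)
    if key is None:
        raise ValueError(f"unknown ICC variant {variant!r}")
    table = table.set_index("Type")
    # pingouin's row/column labels changed across releases
    if key not in table.index:
        key = {"ICC(A,1)": "ICC2", "ICC(C,1)": "ICC3"}[key]
    row = table.loc[key]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    lo, hi = (float(x) for x in row[ci_col])
    return ICCResult(icc=float(row["ICC"]), ci_low=max(lo, -1.0), ci_high=min(hi, 1.0),
                     variant=variant, n_subjects=n, k_raters=2)


# ---------------------------------------------------------------------------
# Pearson correlation with sidedness and Bonferroni families


@dataclass
class CorrelationResult:
    r: float
    p: float
    p_adjusted: float
    sidedness: str
    family_m: int
    n: int

    @property
    def significant(self) -> bool:
        return self.p_adjusted < 0.05


def correlate(x: Sequence[float], y: Sequence[float],
              sidedness: str = "two_sided", family_m: int = 1) -> CorrelationResult:
    """Pearson correlation with t-transform p-value and Bonferroni adjustment.

    ``one_sided_negative`` tests H1: r < 0 (the convention for "higher tau,
    lower score"): it halves the two-sided p when the sample r is negative
    and reports ``1 - p/2`` otherwise.  ``p_adjusted = min(1, family_m * p)``.
    """
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    n = len(xa)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if family_m < 1:
        raise ValueError("family size must be >= 1")
    r, p_two = sps.pearsonr(xa, ya)
    r, p_two = float(r), float(p_two)
    if sidedness == "two_sided":
        p = p_two
    elif sidedness == "one_sided_negative":
        p = p_two / 2.0 if r < 0 else 1.0 - p_two / 2.0
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return CorrelationResult(r=r, p=p, p_adjusted=min(1.0, family_m * p),
                             sidedness=sidedness, family_m=family_m, n=n)


# ---------------------------------------------------------------------------
# clinical staging


def stage_subjects(cohort: pd.DataFrame, diagnosis_col: str = "diagnosis") -> pd.DataFrame:
    """Clinical stage from CDR global: CN at 0, AD at >= 1.

    The conventional rule labels CDR 0.5 both "mildly impaired" and "AD",
    which overlaps; when an explicit diagnosis column is present it resolves
    the 0.5 cases, otherwise they get the documented tie-break label
    ``CDR0.5_unresolved``.  Returns a copy with a ``clinical_stage`` column.
    """
    out = cohort.copy()

    def rule(row) -> str:
        cdr = row["cdr_global"]
        if cdr == 0:
            return "CN"
        if cdr >= 1:
            return "AD"
        if diagnosis_col in row.index and pd.notna(row.get(diagnosis_col)):
            return str(row[diagnosis_col])
        return "CDR0.5_unresolved"

    out["clinical_stage"] = out.apply(rule, axis=1)
    return out


# ---------------------------------------------------------------------------
# quintile stratification


def quintile_stratify(scores: Sequence[float], suvr_wide: pd.DataFrame
                      ) -> pd.DataFrame:
    """Mean SUVR per ROI within quintiles of a memory score.

    Quintile edges sit at the 20/40/60/80th percentiles
    (linear-interpolation percentile definition); a score equal to an edge
    goes to the lower bin.  Returns a frame indexed by quintile (1 = lowest
    scores) with per-ROI mean SUVR and an ``n`` column.  If all scores are
    identical there is a single degenerate bin, flagged by index label
    ``degenerate``.
    """
    s = np.asarray(scores, dtype=np.float64)
    if len(s) != len(suvr_wide):
        raise ValueError("scores and SUVR table must have the same length")
    if np.ptp(s) == 0:
        out = suvr_wide.mean().to_frame().T
        out.index = pd.Index(["degenerate"], name="quintile")
        out["n"] = len(s)
        return out
    edges = np.percentile(s, [20, 40, 60, 80])
    bins = np.searchsorted(edges, s, side="left") + 1  # 1..5, ties -> lower
    out = suvr_wide.copy()
    out["_q"] = bins
    grouped = out.groupby("_q").mean()
    grouped["n"] = out.groupby("_q").size()
    grouped.index.name = "quintile"
    return grouped


# ---------------------------------------------------------------------------
# longitudinal analysis


def change_ratio(pre: float, post: float) -> float:
    """Relative change of a clinical score: ``(post - pre) / (pre + 0.1)``."""
    return (post - pre) / (pre + 0.1)


@dataclass
class LongitudinalRow:
    subject_id: str
    baseline_suvr: Dict[str, float]
    ratios: Dict[str, float]
    followup_days: int
    excluded: bool


DEFAULT_MEASURES = ("mmse", "moca", "recall_durable")


def longitudinal_analysis(cohort: pd.DataFrame, suvr_wide: pd.DataFrame,
                          rois: Sequence[str] = ("EC", "ITG"),
                          measures: Sequence[str] = DEFAULT_MEASURES,
                          max_abs_ratio: float = 0.5
                          ) -> Tuple[List[LongitudinalRow], Dict[Tuple[str, str], CorrelationResult]]:
    """Does baseline regional tau predict later cognitive change?

    Per subject: baseline is the earliest scan; the Pre and Post exams are
    those matched to the earliest and latest scans by minimum absolute date
    difference (ties break toward the earlier exam).  Change ratios use
    :func:`change_ratio`; rows with any ``|ratio| > max_abs_ratio`` are
    excluded as outliers.  Baseline SUVR in each ROI is then correlated with
    each measure's ratio, Bonferroni family ``m = len(rois) * len(measures)``
    (6 for the default 2 ROIs x 3 measures).

    ``cohort`` needs columns subject_id, scan_date, exam_date and the
    measures; ``suvr_wide`` is indexed by subject_id (one baseline row per
    subject) with ROI-role columns.  Subjects with fewer than two scans or
    exams are excluded with a log entry.
    """
    rows: List[LongitudinalRow] = []
    suvr_idx = suvr_wide.reset_index().set_index("subject_id") \
        if "subject_id" not in suvr_wide.index.names else suvr_wide
    for sid, g in cohort.groupby("subject_id", sort=True):
        scans = np.sort(g["scan_date"].unique())
        exams = g.drop_duplicates("exam_date").sort_values("exam_date")
        if len(scans) < 2 or len(exams) < 2:
            logger.info("subject %s excluded: fewer than two scans or exams", sid)
            continue
        if sid not in suvr_idx.index:
            logger.info("subject %s excluded: no baseline SUVR", sid)
            continue

        def match(scan_date: int) -> pd.Series:
            d = (exams["exam_date"] - scan_date).abs()
            # stable ties: minimal |diff|, earlier exam first
            order = exams.assign(_d=d).sort_values(["_d", "exam_date"], kind="stable")
            return order.iloc[0]

        pre = match(int(scans[0]))
        post = match(int(scans[-1]))
        ratios = {m: change_ratio(float(pre[m]), float(post[m])) for m in measures}
        excluded = any(abs(v) > max_abs_ratio for v in ratios.values())
        base = suvr_idx.loc[sid]
        if isinstance(base, pd.DataFrame):
            base = base.iloc[0]
        rows.append(LongitudinalRow(
            subject_id=str(sid),
            baseline_suvr={roi: float(base[roi]) for roi in rois},
            ratios=ratios,
            followup_days=int(scans[-1] - scans[0]),
            excluded=excluded))

    kept = [r for r in rows if not r.excluded]
    family = len(rois) * len(measures)
    results: Dict[Tuple[str, str], CorrelationResult] = {}
    if len(kept) >= 3:
        for roi in rois:
            x = [r.baseline_suvr[roi] for r in kept]
            for m in measures:
                y = [r.ratios[m] for r in kept]
                results[(roi, m)] = correlate(x, y, sidedness="two_sided",
                                              family_m=family)
    else:
        logger.warning("only %d subjects left after exclusions; "
                       "correlations not computed", len(kept))
    return rows, results


# ---------------------------------------------------------------------------
# plain-text report


def report(icc_results: Dict[str, ICCResult],
           correlations: Dict[str, CorrelationResult]) -> str:
    """Human-readable summary mirroring the validation/association tables."""
    lines = ["Intraclass correlation vs ground truth (absolute agreement, single measure)"]
    for name, r in icc_results.items():
        lines.append(f"  {name:14s} ICC {r.icc:6.3f}  (95% CI {r.ci_low:.3f}-{r.ci_high:.3f})")
    lines.append("")
    lines.append("Correlations (Pearson r, Bonferroni-adjusted p)")
    for name, c in correlations.items():
        flag = "*" if c.significant else " "
        lines.append(f"  {name:30s} r {c.r:+.3f}  p_adj {c.p_adjusted:.4f} {flag}")
    return "\n".join(lines)
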