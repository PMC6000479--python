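"""Test-retest reliability for two-occasion score tables.

Per measure, from the participants with valid scores at both occasions:

* **Practice effect** — paired two-tailed t test on occasion-1 vs
  occasion-2 scores; a significant (p < .05) *improvement* indicates a
  practice effect.
* **ICC** — intraclass correlation, two-way model, absolute agreement,
  single measures (McGraw & Wong's ICC(A,1)), computed from the two-way
  ANOVA mean squares.  Absolute agreement penalizes systematic occasion
  shifts, so practice effects count as error.
* **SEM** — standard error of measurement, ``sqrt(MS_residual)``, in raw
  score units.
* **SDC** — smallest detectable change, ``1.96 * sqrt(2) * SEM``; the
  group variant divides by ``sqrt(n)`` and, for measures with a
  significant practice effect, first adds the |mean1 - mean2| difference
  so that group change must also exceed the expected practice gain.
* **Retest correlation** — Pearson r, or Spearman rho when either
  occasion's scores fail a Shapiro-Wilk normality check at alpha = .05.

All statistics are computed on raw scores (means, SEMs and SDCs are in the
instrument's units); the battery composite is handled as a derived measure
on the standardized scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    COMPOSITE_MEASURE,
    Direction,
    InsufficientDataError,
    MeasureSpec,
    ReliabilityResult,
    ScoreTable,
    ValidationError,
    VarianceDecomposition,
)
from . import scaling

logger = logging.getLogger("acsnorms")

SDC_FACTOR = 1.96 * math.sqrt(2.0)

__all__ = [
    "anova_decompose", "icc_absolute_agreement", "practice_test",
    "sem_from_decomp", "sdc", "sdc_group", "retest_correlation",
    "reliability_report", "PracticeTestResult", "RetestSummary",
    "acs_reference_reliability", "SDC_FACTOR",
]


def _as_pairs(pairs) -> np.ndarray:
    if isinstance(pairs, pd.DataFrame):
        arr = pairs[["score1", "score2"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("pairs must be an (n, 2) array of scores")
    if not np.isfinite(arr).all():
        raise ValidationError("pairs must be finite")
    return arr


def anova_decompose(pairs) -> VarianceDecomposition:
    """Two-way ANOVA mean squares for an n x 2 test-retest table.

    Rows are subjects, columns the two occasions.  Requires >= 3 complete
    pairs.
    """
    arr = _as_pairs(pairs)
    n, k = arr.shape
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {n}")
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    resid = arr - row_means[:, None] - col_means[None, :] + grand
    ss_error = float((resid ** 2).sum())
    return VarianceDecomposition(
        ms_rows=ss_rows / (n - 1),
        ms_cols=ss_cols / (k - 1),
        ms_error=max(ss_error / ((n - 1) * (k - 1)), 0.0),
        n_subjects=n,
        k_occasions=k,
    )


def icc_absolute_agreement(decomp: VarianceDecomposition) -> float:
    """ICC(A,1): single-measures, two-way, absolute agreement.

    ``(MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))``.  A zero
    denominator (all scores identical) is defined as perfect agreement.
    """
    msr, msc, mse = decomp.ms_rows, decomp.ms_cols, decomp.ms_error
    k, n = decomp.k_occasions, decomp.n_subjects
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        logger.warning("ICC denominator is zero (all scores identical); "
                       "defining ICC = 1")
        return 1.0
    return (msr - mse) / denom


@dataclass(frozen=True)
class PracticeTestResult:
    t_stat: float
    df: int
    p_value: float
    practice_effect: bool

    def __iter__(self):
        return iter((self.t_stat, self.df, self.p_value, self.practice_effect))


def practice_test(pairs, alpha: float = 0.05,
                  direction: Direction | None = None) -> PracticeTestResult:
    """Paired two-tailed t test of occasion-1 vs occasion-2 scores.

    ``t > 0`` means occasion-1 scores were higher.  A practice effect is a
    significant result that is also an *improvement* when ``direction`` is
    given (occasion-2 better); without a direction any significant shift
    counts.  Zero variance of the differences leaves p undefined and
    ``practice_effect=False`` with a warning.
    """
    arr = _as_pairs(pairs)
    if arr.shape[0] < 2:
        raise InsufficientDataError("paired test needs >= 2 pairs")
    diff = arr[:, 0] - arr[:, 1]
    n = len(diff)
    if float(diff.std(ddof=1)) == 0.0:
        if float(diff.mean()) == 0.0:
            return PracticeTestResult(0.0, n - 1, float("nan"), False)
        logger.warning("zero variance of paired differences with nonzero "
                       "mean; p undefined, practice effect not claimed")
        return PracticeTestResult(float("nan"), n - 1, float("nan"), False)
    t_stat, p_value = stats.ttest_rel(arr[:, 0], arr[:, 1])
    t_stat, p_value = float(t_stat), float(p_value)
    improved = True
    if direction is not None:
        mean_diff = float(diff.mean())  # mean1 - mean2
        if Direction(direction) is Direction.HIGHER_IS_BETTER:
            improved = mean_diff < 0
        else:
            improved = mean_diff > 0
    return PracticeTestResult(t_stat, n - 1, p_value,
                              bool(p_value < alpha and improved))


def sem_from_decomp(decomp: VarianceDecomposition) -> float:
    """Standard error of measurement: ``sqrt(MS_residual)``, raw units."""
    return math.sqrt(decomp.ms_error)


def sdc(sem: float) -> float:
    """Smallest detectable change, ``1.96 * sqrt(2) * SEM``."""
    if sem < 0:
        raise ValidationError("sem must be >= 0")
    return SDC_FACTOR * sem


def sdc_group(sem: float, n: int, mean1: float = 0.0, mean2: float = 0.0,
              practice_effect: bool = False) -> float:
    """Group-level SDC: ``(SDC + |mean1 - mean2| * practice) / sqrt(n)``.

    Averaging over n participants shrinks measurement error by ``sqrt(n)``;
    when a practice effect is present the expected mean practice gain is
    added to the detectability threshold first.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    adjust = abs(mean1 - mean2) if practice_effect else 0.0
    return (sdc(sem) + adjust) / math.sqrt(n)


def retest_correlation(pairs, method: str = "auto",
                       normality_alpha: float = 0.05) -> tuple[float, str]:
    """Occasion-1/occasion-2 correlation.

    ``method='auto'`` uses Pearson r unless either occasion's scores fail
    Shapiro-Wilk normality at ``normality_alpha``, in which case Spearman
    rho is reported.  Zero variance at either occasion leaves the
    correlation undefined (NaN).
    """
    arr = _as_pairs(pairs)
    if arr.shape[0] < 3:
        raise InsufficientDataError("correlation needs >= 3 pairs")
    if method not in ("auto", "pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if arr[:, 0].std() == 0.0 or arr[:, 1].std() == 0.0:
        logger.warning("zero variance at an occasion; correlation undefined")
        chosen = method if method != "auto" else "pearson"
        return (float("nan"), chosen)
    if method == "auto":
        normal = all(stats.shapiro(arr[:, j]).pvalue >= normality_alpha
                     for j in (0, 1))
        method = "pearson" if normal else "spearman"
    if method == "pearson":
        r = stats.pearsonr(arr[:, 0], arr[:, 1]).statistic
    else:
        r = stats.spearmanr(arr[:, 0], arr[:, 1]).statistic
    return (float(r), method)


def _measure_result(measure: str, pairs: pd.DataFrame,
                    direction: Direction | None,
                    alpha_practice: float,
                    corr_method: str) -> ReliabilityResult:
    arr = _as_pairs(pairs)
    decomp = anova_decompose(arr)
    sem = sem_from_decomp(decomp)
    mean1, mean2 = float(arr[:, 0].mean()), float(arr[:, 1].mean())
    sd1 = float(arr[:, 0].std(ddof=1))
    sd2 = float(arr[:, 1].std(ddof=1))
    ptest = practice_test(arr, alpha=alpha_practice, direction=direction)
    corr, corr_type = retest_correlation(arr, method=corr_method)
    return ReliabilityResult(
        measure=measure,
        n_pairs=decomp.n_subjects,
        mean1=mean1, sd1=sd1, mean2=mean2, sd2=sd2,
        t_stat=ptest.t_stat, df=ptest.df, p_value=ptest.p_value,
        practice_effect=ptest.practice_effect,
        sem=sem, sdc=sdc(sem),
        sdc_group=sdc_group(sem, decomp.n_subjects, mean1, mean2,
                            ptest.practice_effect),
        icc=icc_absolute_agreement(decomp),
        corr=corr, corr_type=corr_type,
    )


def reliability_report(
    table: ScoreTable,
    battery: Sequence[MeasureSpec],
    alpha_corr: float = 0.01,
    alpha_practice: float = 0.05,
    corr_method: str = "auto",
    include_composite: bool = True,
) -> list[ReliabilityResult]:
    """One :class:`ReliabilityResult` per measure with >= 3 complete pairs.

    Only participants non-excluded at *both* occasions for a measure
    contribute to its statistics.  The composite is derived from the
    standardized table (occasion-1 reference constants) for participants
    with complete composite data at both occasions.  ``alpha_corr`` is the
    significance level reliability correlations are reported against.
    """
    if 2 not in table.occasions:
        raise ValidationError("reliability requires both assessment occasions")
    by_name = {m.name: m for m in battery}
    results: list[ReliabilityResult] = []
    for spec in battery:
        if spec.name == COMPOSITE_MEASURE:
            continue
        if spec.name not in table.measures:
            continue
        pairs = table.pairs(spec.name)
        if len(pairs) < 3:
            logger.warning("%s: only %d complete pairs, skipped",
                           spec.name, len(pairs))
            continue
        results.append(_measure_result(spec.name, pairs, spec.direction,
                                       alpha_practice, corr_method))
    if include_composite:
        ztable = scaling.standardized_table(table, battery)
        comp = scaling.composite_by_occasion(ztable, battery)
        wide = comp.pivot(index="participant_id", columns="occasion", values="z")
        if {1, 2} <= set(wide.columns):
            pairs = wide[[1, 2]].dropna().rename(columns={1: "score1", 2: "score2"})
            if len(pairs) >= 3:
                results.append(_measure_result(
                    COMPOSITE_MEASURE, pairs, Direction.HIGHER_IS_BETTER,
                    alpha_practice, corr_method))
            else:
                logger.warning("composite: fewer than 3 complete pairs, skipped")
    return results


def report_to_frame(results: Sequence[ReliabilityResult]) -> pd.DataFrame:
    """Tabular (CSV-ready) view of a reliability report."""
    return pd.DataFrame([vars(r).copy() for r in results])


# ---------------------------------------------------------------------------
# published ACS reference reliability summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RetestSummary:
    """Published test-retest summary statistics for one ACS measure
    (reference normative sample; raw score units)."""

    measure: str
    n_pairs: int
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    sem: float
    icc: float
    practice_effect: bool

    def group_sdc(self) -> float:
        """Group SDC recomputed from the published summary."""
        return sdc_group(self.sem, self.n_pairs, self.mean1, self.mean2,
                         self.practice_effect)


def acs_reference_reliability() -> dict[str, RetestSummary]:
    """Published ACS reference-sample test-retest summaries.

    Means/SDs and SEMs are in raw instrument units; ``practice_effect``
    records whether the paired t test on the reference sample was a
    significant improvement.  These are inputs for reproducing the
    published SDC arithmetic and for calibrating the cohort simulator.
    """
    rows = [
        # measure, n, mean1, sd1, mean2, sd2, sem, icc, practice
        ("ConnectTheDotsI", 240, 34.83, 9.39, 32.48, 7.79, 4.76, 0.67, True),
        ("ConnectTheDotsII", 246, 58.05, 18.45, 54.95, 17.62, 9.55, 0.71, True),
        ("WordlistLearning", 241, 52.02, 10.13, 58.11, 9.80, 5.44, 0.59, True),
        ("WordlistDelayedRecall", 241, 11.15, 2.71, 12.09, 2.88, 3.69, 0.50, True),
        ("WordlistRecognition", 242, 44.17, 1.57, 44.31, 1.72, 0.90, 0.70, False),
        ("ReactionSpeed", 241, 308.88, 44.57, 310.49, 44.85, 25.60, 0.67, False),
        ("PlaceTheBeads", 143, 25.63, 14.03, 21.54, 15.81, 11.15, 0.45, True),
        ("BoxTapping", 232, 9.17, 2.26, 9.70, 1.91, 1.47, 0.49, True),
        ("FillTheGrid", 241, 62.59, 12.69, 60.73, 11.42, 5.30, 0.80, True),
        ("DigitSequencesI", 245, 10.40, 2.22, 10.61, 2.17, 1.49, 0.54, False),
        ("DigitSequencesII", 242, 8.50, 2.72, 8.78, 2.87, 1.68, 0.64, False),
        (COMPOSITE_MEASURE, 206, 0.06, 0.53, 0.07, 0.55, 0.05, 0.83, False),
    ]
    return {r[0]: RetestSummary(*r) for r in rows}
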