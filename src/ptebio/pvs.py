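"""Perivascular-space (PVS) hemispheric asymmetry statistics.

For each subject the marked PVSs are split by hemisphere; the hemispheric
ratio HR of each side is its count over the whole-brain total, the asymmetry
index AI = HR_major - HR_minor lies in [0, 1], and AI >= 0.2 (one hemisphere
holding more than 60% of all PVSs) defines high-grade asymmetry. Mean calibers
per hemisphere give |C_diff|, whose correlation with AI across subjects is the
caliber-asymmetry relationship of interest. Cohort-level comparisons use the
classical equal-variance Student's t-test (Welch available behind a flag) and
Pearson correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ArgumentError
from .io import PVSMarkerTable

logger = logging.getLogger(__name__)

HIGH_AI_THRESHOLD = 0.2
INTERMEDIATE_AI_THRESHOLD = 0.1


def hemispheric_ratios(pvs_right: int, pvs_left: int
                       ) -> tuple[float, float, float, float]:
    """(hr_right, hr_left, hr_minor, hr_major) from hemisphere counts.

    Each HR is the hemisphere count over the whole-brain total; minor/major
    are the smaller/larger of the pair (both 0.5 on an exact tie).
    """
    if pvs_right < 0 or pvs_left < 0:
        raise ArgumentError("counts must be non-negative")
    total = pvs_right + pvs_left
    if total < 1:
        raise ArgumentError("subject has zero PVSs; hemispheric ratios undefined")
    hr_right = pvs_right / total
    hr_left = pvs_left / total
    return hr_right, hr_left, min(hr_right, hr_left), max(hr_right, hr_left)


def asymmetry_index(hr_minor: float, hr_major: float) -> float:
    """AI = HR_major - HR_minor, in [0, 1]."""
    if not math.isclose(hr_minor + hr_major, 1.0, abs_tol=1e-12):
        raise ArgumentError("hemispheric ratios must sum to 1")
    if hr_minor > hr_major:
        raise ArgumentError("hr_minor must not exceed hr_major")
    return hr_major - hr_minor


def classify_asymmetry(ai: float,
                       high_threshold: float = HIGH_AI_THRESHOLD,
                       intermediate_threshold: float = INTERMEDIATE_AI_THRESHOLD
                       ) -> str:
    """Grade an asymmetry index as "low", "intermediate", or "high".

    High means AI >= high_threshold (boundary inclusive). The intermediate
    band [intermediate_threshold, high_threshold) is a toolkit convention;
    only the high threshold has a literature-anchored default (0.2).
    """
    if not (0 <= ai <= 1):
        raise ArgumentError("AI must lie in [0, 1]")
    if not (0 < intermediate_threshold < high_threshold):
        raise ArgumentError("need 0 < intermediate_threshold < high_threshold")
    # AI is a ratio of integer counts; honor boundary inclusion up to float
    # representation error (e.g. 60/100 - 40/100 prints as 0.19999...98)
    eps = 1e-12
    if ai >= high_threshold - eps:
        return "high"
    if ai >= intermediate_threshold - eps:
        return "intermediate"
    return "low"


def caliber_stats(table: PVSMarkerTable
                  ) -> tuple[float, float, float, dict[str, np.ndarray]]:
    """(c_right, c_left, c_diff_abs, per-hemisphere caliber samples) in mm.

    A hemisphere with no markers yields NaN for its mean and for |C_diff|.
    """
    samples = {h: table.calibers(h) for h in ("right", "left")}
    c_right = float(samples["right"].mean()) if samples["right"].size else float("nan")
    c_left = float(samples["left"].mean()) if samples["left"].size else float("nan")
    if samples["right"].size and samples["left"].size:
        c_diff = abs(c_right - c_left)
    else:
        c_diff = float("nan")
        logger.warning("subject %s: |C_diff| undefined (empty hemisphere)",
                       table.subject_id)
    return c_right, c_left, c_diff, samples


@dataclass
class SubjectAsymmetry:
    """Per-subject asymmetry summary derived from a marker table."""

    subject_id: str
    group: str
    age_years: float
    sex: str
    pvs_right: int
    pvs_left: int
    pvs_tot: int
    hr_right: float
    hr_left: float
    hr_minor: float
    hr_major: float
    ai: float
    c_right: float
    c_left: float
    c_diff_abs: float
    grade: str


def subject_asymmetry(table: PVSMarkerTable,
                      high_threshold: float = HIGH_AI_THRESHOLD,
                      intermediate_threshold: float = INTERMEDIATE_AI_THRESHOLD
                      ) -> SubjectAsymmetry:
    """Full per-subject asymmetry row (counts, HRs, AI, calibers, grade)."""
    r, l = table.counts()
    hr_r, hr_l, hr_min, hr_maj = hemispheric_ratios(r, l)
    ai = asymmetry_index(hr_min, hr_maj)
    c_r, c_l, c_diff, _ = caliber_stats(table)
    return SubjectAsymmetry(
        subject_id=table.subject_id, group=table.group,
        age_years=table.age_years, sex=table.sex,
        pvs_right=r, pvs_left=l, pvs_tot=r + l,
        hr_right=hr_r, hr_left=hr_l, hr_minor=hr_min, hr_major=hr_maj,
        ai=ai, c_right=c_r, c_left=c_l, c_diff_abs=c_diff,
        grade=classify_asymmetry(ai, high_threshold, intermediate_threshold),
    )


def cohort_compare(group_a: Sequence[float], group_b: Sequence[float],
                   welch: bool = False
                   ) -> tuple[float, float, tuple[float, float],
                              tuple[float, float]]:
    """Two-sample t-test between subject-level metrics of two groups.

    Returns (t, p, (mean_a, mean_b), (sd_a, sd_b)); SDs use ddof=1. The
    default is the classical equal-variance Student's test; ``welch=True``
    drops the equal-variance assumption.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ArgumentError("each group needs at least 2 subjects")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return (float(t), float(p),
            (float(a.mean()), float(b.mean())),
            (float(a.std(ddof=1)), float(b.std(ddof=1))))


def cohort_compare_from_stats(mean_a: float, sd_a: float, n_a: int,
                              mean_b: float, sd_b: float, n_b: int,
                              welch: bool = False) -> tuple[float, float]:
    """Equal-variance (or Welch) t-test from printed summary statistics."""
    if n_a < 2 or n_b < 2:
        raise ArgumentError("each group needs at least 2 subjects")
    t, p = stats.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                      equal_var=not welch)
    return float(t), float(p)


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with two-sided t-based p-value.

    Returns (nan, nan) with a logged report if either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ArgumentError("need equal-length vectors with >= 3 entries")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ArgumentError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("correlation undefined: zero variance in an input")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def subject_caliber_test(table: PVSMarkerTable,
                         welch: bool = False) -> tuple[float, float]:
    """Within-subject t-test between right- and left-hemisphere calibers.

    Returns (nan, nan) with a logged report when a hemisphere has fewer than
    two markers.
    """
    r = table.calibers("right")
    l = table.calibers("left")
    if r.size < 2 or l.size < 2:
        logger.warning("subject %s: caliber test undefined "
                       "(<2 markers in a hemisphere)", table.subject_id)
        return float("nan"), float("nan")
    if np.ptp(r) == 0 and np.ptp(l) == 0 and r[0] == l[0]:
        return 0.0, 1.0  # identical constant samples
    t, p = stats.ttest_ind(r, l, equal_var=not welch)
    return float(t), float(p)


@dataclass
class CohortReport:
    """Every cohort-level quantity the asymmetry analysis reports."""

    subjects: list[SubjectAsymmetry]
    excluded_subjects: list[str]
    group_totals: dict[str, tuple[float, float]]       # group -> (mean, sd)
    totals_ttest: tuple[float, float] | None
    hr_range: dict[str, tuple[float, float]]           # group -> (min, max) HR
    mean_hr_minor: dict[str, float]
    mean_hr_major: dict[str, float]
    mean_ai: dict[str, float]
    ai_ttest: tuple[float, float] | None
    group_caliber: dict[str, tuple[float, float]]      # per-subject mean calibers
    caliber_ttest: tuple[float, float] | None
    ai_vs_cdiff: tuple[float, float] | None            # Pearson r, p
    age_vs_total: tuple[float, float] | None
    n_high_asymmetry: dict[str, int]
    per_subject_caliber_tests: dict[str, tuple[float, float]]
    significant_caliber_subjects: list[str] = field(default_factory=list)


def cohort_report(tables: Sequence[PVSMarkerTable],
                  high_threshold: float = HIGH_AI_THRESHOLD,
                  intermediate_threshold: float = INTERMEDIATE_AI_THRESHOLD,
                  welch: bool = False) -> CohortReport:
    """Compute the full asymmetry battery on a cohort of marker tables.

    Subjects with zero in-range markers are excluded (reported, never graded).
    Group tests needing two groups with >= 2 subjects are set to None when the
    cohort cannot support them; per-subject rows are always emitted.
    """
    subjects: list[SubjectAsymmetry] = []
    excluded: list[str] = []
    caliber_tests: dict[str, tuple[float, float]] = {}
    for t in tables:
        if len(t.markers) == 0:
            excluded.append(t.subject_id)
            logger.warning("subject %s excluded: zero in-range PVS markers",
                           t.subject_id)
            continue
        subjects.append(subject_asymmetry(t, high_threshold,
                                          intermediate_threshold))
        caliber_tests[t.subject_id] = subject_caliber_test(t, welch=welch)

    groups = sorted({s.group for s in subjects})

    def by_group(metric) -> dict[str, np.ndarray]:
        return {g: np.array([metric(s) for s in subjects if s.group == g])
                for g in groups}

    totals = by_group(lambda s: s.pvs_tot)
    ais = by_group(lambda s: s.ai)
    hr_pairs = {g: np.array([[s.hr_minor, s.hr_major]
                             for s in subjects if s.group == g])
                for g in groups}
    mean_calibers = {g: np.array([np.nanmean([s.c_right, s.c_left])
                                  for s in subjects if s.group == g])
                     for g in groups}

    def two_group_test(data: dict[str, np.ndarray]):
        if len(groups) == 2 and all(v.size >= 2 for v in data.values()):
            t, p, _, _ = cohort_compare(data[groups[0]], data[groups[1]],
                                        welch=welch)
            return t, p
        return None

    ai_cdiff = None
    finite = [s for s in subjects if np.isfinite(s.c_diff_abs)]
    if len(finite) >= 3:
        ai_cdiff = correlate([s.ai for s in finite],
                             [s.c_diff_abs for s in finite])
    age_total = None
    if len(subjects) >= 3:
        age_total = correlate([s.age_years for s in subjects],
                              [s.pvs_tot for s in subjects])

    return CohortReport(
        subjects=subjects,
        excluded_subjects=excluded,
        group_totals={g: (float(v.mean()), float(v.std(ddof=1)) if v.size > 1
                          else float("nan")) for g, v in totals.items()},
        totals_ttest=two_group_test(totals),
        hr_range={g: (float(v.min()), float(v.max()))
                  for g, v in hr_pairs.items()},
        mean_hr_minor={g: float(v[:, 0].mean()) for g, v in hr_pairs.items()},
        mean_hr_major={g: float(v[:, 1].mean()) for g, v in hr_pairs.items()},
        mean_ai={g: float(v.mean()) for g, v in ais.items()},
        ai_ttest=two_group_test(ais),
        group_caliber={g: (float(np.nanmean(v)),
                           float(np.nanstd(v, ddof=1)) if v.size > 1
                           else float("nan"))
                       for g, v in mean_calibers.items()},
        caliber_ttest=two_group_test(mean_calibers),
        ai_vs_cdiff=ai_cdiff,
        age_vs_total=age_total,
        n_high_asymmetry={g: sum(1 for s in subjects
                                 if s.group == g and s.grade == "high")
                          for g in groups},
        per_subject_caliber_tests=caliber_tests,
        significant_caliber_subjects=[sid for sid, (_, p) in
                                      caliber_tests.items()
                                      if np.isfinite(p) and p < 0.05],
    )
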