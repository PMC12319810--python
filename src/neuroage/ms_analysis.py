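"""Cross-sectional and longitudinal brain-age analyses for multiple sclerosis.

Given per-visit brain-age predictions and clinical scores, this module
computes per-subject annual brain-age change, classifies confirmed
disability worsening from EDSS and timed-test changes, stratifies subjects
by disease duration, compares paired prediction series (e.g. lesion-filled
vs. original scans), and assembles the longitudinal report: mean annual
change with a bootstrap confidence interval, a one-sample t-test against
the 1 year/year rate of healthy chronological aging, and group contrasts.

Disability worsening follows the standard composite rule: an EDSS increase
of >= 1.0 when baseline EDSS < 6.0, or >= 0.5 when baseline EDSS >= 6.0,
or a >= 20% slowing on the Timed 25-Foot Walk or the Nine-Hole Peg Test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import stats
from .errors import DomainError, MissingDataError, ShapeError

__all__ = [
    "ClinicalVisit",
    "VisitPair",
    "annual_change",
    "classify_worsening",
    "stratify_duration",
    "compare_paired_predictions",
    "longitudinal_report",
    "EDSS_STEP_THRESHOLD",
    "TIMED_TEST_WORSENING_FRACTION",
]

# EDSS baseline at or above which a 0.5-step increase already counts as
# worsening; below it a full 1.0-step increase is required.
EDSS_STEP_THRESHOLD = 6.0
# Relative slowing of T25FW or 9HPT that counts as worsening (inclusive).
TIMED_TEST_WORSENING_FRACTION = 0.20


@dataclass(frozen=True)
class ClinicalVisit:
    """One clinical assessment.

    EDSS lies on the 0-10 lattice in 0.5 steps (higher is worse); SDMT is a
    correct-symbol count (higher is better); 9HPT and T25FW are times in
    seconds (longer is worse).
    """

    subject_id: str
    visit: int
    edss: float | None
    sdmt: float | None
    nhpt: float | None
    t25fw: float | None

    def __post_init__(self):
        if self.edss is not None:
            if not 0.0 <= self.edss <= 10.0 or (self.edss * 2) % 1 != 0:
                raise DomainError(
                    f"EDSS must be on the 0-10 half-point lattice, got {self.edss}"
                )
        for name in ("nhpt", "t25fw"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DomainError(f"{name} must be positive, got {v}")


@dataclass(frozen=True)
class VisitPair:
    """Baseline and follow-up brain ages for one subject."""

    subject_id: str
    baseline_brain_age: float
    followup_brain_age: float
    interval_years: float
    baseline_visit: ClinicalVisit | None = None
    followup_visit: ClinicalVisit | None = None


def annual_change(pair: VisitPair) -> float:
    """Annual brain-age change: (follow-up - baseline) / interval, in
    brain-age years per chronological year."""
    if pair.interval_years <= 0:
        raise DomainError(
            f"interval must be positive, got {pair.interval_years}"
        )
    return (pair.followup_brain_age - pair.baseline_brain_age) / pair.interval_years


def _require(visit: ClinicalVisit, name: str) -> float:
    value = getattr(visit, name)
    if value is None:
        raise MissingDataError(
            f"{name} missing for subject {visit.subject_id} visit {visit.visit}"
        )
    return value


def classify_worsening(
    baseline: ClinicalVisit, followup: ClinicalVisit
) -> bool:
    """Confirmed disability worsening between two visits.

    True iff EDSS increased by >= 1.0 (baseline EDSS < 6.0) or >= 0.5
    (baseline EDSS >= 6.0), or T25FW or 9HPT slowed by >= 20% of baseline.
    All three components must be present; missing data raises
    MissingDataError rather than being silently skipped.
    """
    if baseline.subject_id != followup.subject_id:
        raise DomainError("visits belong to different subjects")
    edss0 = _require(baseline, "edss")
    edss1 = _require(followup, "edss")
    d_edss = edss1 - edss0
    if edss0 < EDSS_STEP_THRESHOLD:
        edss_worse = d_edss >= 1.0
    else:
        edss_worse = d_edss >= 0.5
    timed_worse = False
    for name in ("t25fw", "nhpt"):
        t0 = _require(baseline, name)
        t1 = _require(followup, name)
        if (t1 - t0) >= TIMED_TEST_WORSENING_FRACTION * t0:
            timed_worse = True
    return bool(edss_worse or timed_worse)


def stratify_duration(
    durations: Mapping[str, float], cutoff: float = 6.0
) -> tuple[list[str], list[str]]:
    """Split subjects into early (< cutoff years) and longstanding
    (>= cutoff) disease-duration groups.

    The boundary value is assigned to the longstanding group.
    """
    early, longstanding = [], []
    for subject, duration in durations.items():
        if duration < 0:
            raise DomainError(f"negative disease duration for {subject}")
        (early if duration < cutoff else longstanding).append(subject)
    return early, longstanding


def compare_paired_predictions(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float, float]:
    """Agreement summaries for two prediction series on the same scans.

    Returns (Spearman rho, mean difference b - a, mean absolute
    difference). Used e.g. for lesion-filled vs. original images and for
    3T vs. 7T acquisitions of the same subjects.
    """
    av = np.asarray(a, dtype=float).ravel()
    bv = np.asarray(b, dtype=float).ravel()
    if av.size != bv.size:
        raise ShapeError(f"length mismatch: {av.size} vs {bv.size}")
    if av.size < 3:
        raise ShapeError("paired comparison requires n >= 3")
    rho, _ = stats.correlation(av, bv, method="spearman")
    diff = bv - av
    return rho, float(np.mean(diff)), float(np.mean(np.abs(diff)))


def longitudinal_report(
    pairs: Sequence[VisitPair],
    durations: Mapping[str, float] | None = None,
    duration_cutoff: float = 6.0,
    n_resamples: int = 1000,
    seed: int = 0,
) -> dict:
    """Longitudinal summary of per-subject annual brain-age change.

    Computes the mean annual change with its IQR and a percentile bootstrap
    95% CI, tests the mean against 1 year/year (one-sample t-test), and,
    where clinical visits / disease durations are available, contrasts
    worsening vs. stable and early vs. longstanding subgroups with the
    Mann-Whitney U test. All subgroup-contrast p-values are jointly
    Benjamini-Hochberg adjusted.
    """
    if len(pairs) < 2:
        raise DomainError("longitudinal_report requires >= 2 visit pairs")
    subjects = [p.subject_id for p in pairs]
    rates = np.array([annual_change(p) for p in pairs])

    if np.std(rates, ddof=1) == 0:
        # all subjects changed at exactly the same rate: the t statistic
        # degenerates to a signed infinity (or 0 when the rate equals 1)
        delta = float(rates.mean() - 1.0)
        t_stat = math.copysign(math.inf, delta) if delta != 0 else 0.0
        t_p = 0.0 if delta != 0 else 1.0
    else:
        t_stat, t_p = stats.one_sample_t(rates, 1.0)
    ci = stats.bootstrap_ci(
        rates, np.mean, n_resamples=n_resamples, level=0.95, seed=seed
    )
    q1, q3 = np.quantile(rates, [0.25, 0.75])
    report: dict = {
        "n_subjects": len(pairs),
        "mean_annual_change": float(np.mean(rates)),
        "sd_annual_change": float(np.std(rates, ddof=1)),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(q3 - q1),
        "ci95": [ci[0], ci[1]],
        "t_vs_1": t_stat,
        "p_vs_1": t_p,
        "annual_change_by_subject": dict(zip(subjects, rates.tolist())),
    }

    contrasts: dict[str, dict] = {}
    raw_ps: list[float] = []

    has_clinical = all(
        p.baseline_visit is not None and p.followup_visit is not None
        for p in pairs
    )
    if has_clinical:
        worsened = np.array(
            [classify_worsening(p.baseline_visit, p.followup_visit) for p in pairs]
        )
        if worsened.any() and (~worsened).any():
            u, p_val, rb = stats.mann_whitney(rates[worsened], rates[~worsened])
            contrasts["worsening_vs_stable"] = {
                "n_worsening": int(worsened.sum()),
                "n_stable": int((~worsened).sum()),
                "mean_worsening": float(rates[worsened].mean()),
                "mean_stable": float(rates[~worsened].mean()),
                "u": u,
                "rank_biserial": rb,
                "p": p_val,
            }
            raw_ps.append(p_val)
        report["n_worsening"] = int(worsened.sum())

    if durations is not None:
        early_ids, long_ids = stratify_duration(
            {s: durations[s] for s in subjects if s in durations},
            cutoff=duration_cutoff,
        )
        early = np.isin(subjects, early_ids)
        longst = np.isin(subjects, long_ids)
        if early.any() and longst.any():
            u, p_val, rb = stats.mann_whitney(rates[early], rates[longst])
            contrasts["early_vs_longstanding"] = {
                "n_early": int(early.sum()),
                "n_longstanding": int(longst.sum()),
                "mean_early": float(rates[early].mean()),
                "mean_longstanding": float(rates[longst].mean()),
                "u": u,
                "rank_biserial": rb,
                "p": p_val,
            }
            raw_ps.append(p_val)

    if raw_ps:
        adjusted = stats.bh_fdr(raw_ps)
        for contrast, p_adj in zip(contrasts.values(), adjusted):
            contrast["p_adjusted"] = float(p_adj)
    report["contrasts"] = contrasts
    return report
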