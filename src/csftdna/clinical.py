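"""Leptomeningeal-disease classification and clinical statistics.

Implements the study's LMD status rules (definitive / possible and the
EANO-ESMO confirmed / probable / possible mapping), diagnostic-modality
sensitivity, Kaplan-Meier / log-rank survival comparisons with a
Mantel-Haenszel hazard ratio, rank-based association tests, drug
CSF-penetration rate and on-treatment VAF change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import UndefinedResultError, ValidationError


@dataclass
class PatientClinical:
    """One patient's clinical record; ``None`` marks an unknown field."""

    patient_id: str
    cytology_positive: bool | None = None
    egfr_csf_pcr_positive: bool | None = None
    mri_unequivocal_lmd: bool | None = None
    progressive_symptoms: bool | None = None
    os_time_days: float | None = None
    os_event: bool | None = None
    cns_progression_time_days: float | None = None
    cns_event: bool | None = None
    csf_osimertinib_nM: float | None = None
    plasma_osimertinib_nM: float | None = None

    def __post_init__(self) -> None:
        for name in ("os_time_days", "cns_progression_time_days",
                     "csf_osimertinib_nM", "plasma_osimertinib_nM"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{self.patient_id}: {name} must be >= 0")


@dataclass(frozen=True)
class LMDStatus:
    study_category: str  # definitive | possible | non_lmd
    eano_esmo: str  # confirmed | probable | possible | none
    data_complete: bool = True


@dataclass(frozen=True)
class SurvivalComparison:
    hazard_ratio: float | None
    hr_ci_low: float | None
    hr_ci_high: float | None
    logrank_p: float
    n_group1: int
    n_group2: int
    endpoint: str = "OS"
    #: Cox partial-likelihood HR; unlike the O/E form it does not attenuate
    #: large effects, so it is the field to use for effect-size recovery
    cox_hazard_ratio: float | None = None


@dataclass(frozen=True)
class AssociationResult:
    statistic: float
    p_value: float
    n: int
    kind: str = "spearman"


def classify_lmd(record: PatientClinical) -> LMDStatus:
    """Classify a patient's LMD status under both schemes.

    Study scheme: definitive requires positive cytology or a positive
    clinical EGFR CSF PCR, or unequivocal MRI evidence together with
    progressive neurological symptoms; remaining patients with symptoms or
    MRI findings are possible; otherwise non-LMD.  EANO-ESMO: confirmed means
    cytology-positive; probable means cytology-negative with MRI findings and
    symptoms; possible means symptoms with negative cytology and MRI.
    Unknown fields count as negative and clear the completeness flag.
    """
    fields = (record.cytology_positive, record.egfr_csf_pcr_positive,
              record.mri_unequivocal_lmd, record.progressive_symptoms)
    complete = all(v is not None for v in fields)
    cyt, pcr, mri, sym = (bool(v) for v in fields)

    if cyt or pcr or (mri and sym):
        study = "definitive"
    elif mri or sym:
        study = "possible"
    else:
        study = "non_lmd"

    if cyt:
        eano = "confirmed"
    elif mri and sym:
        eano = "probable"
    elif sym and not mri:
        eano = "possible"
    else:
        eano = "none"
    return LMDStatus(study_category=study, eano_esmo=eano, data_complete=complete)


def modality_sensitivity(
    cohort: Iterable[tuple[LMDStatus, bool | None]],
) -> tuple[float, int, int]:
    """Sensitivity of a modality among evaluable definitive-LMD patients.

    Returns (sensitivity, numerator, denominator); patients whose modality
    result is ``None`` are not evaluable and drop from the denominator.
    """
    num = den = 0
    for status, result in cohort:
        if status.study_category != "definitive" or result is None:
            continue
        den += 1
        num += int(bool(result))
    if den == 0:
        raise UndefinedResultError("no evaluable definitive-LMD cases")
    return num / den, num, den


def logrank_table(times: np.ndarray, events: np.ndarray,
                  group: np.ndarray) -> tuple[float, float, float, float, float]:
    """Observed/expected event counts and variance for a two-group log-rank test.

    Returns (O1, E1, O2, E2, V) using the hypergeometric variance at each
    distinct event time (standard tie handling).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group = np.asarray(group)
    o1 = e1 = o2 = v = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        dead = events & (times == t)
        d = dead.sum()
        d1 = (dead & (group == 1)).sum()
        o1 += d1
        o2 += d - d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    e2 = (o1 + o2) - e1
    return o1, e1, o2, e2, v


def km_logrank(times: Sequence[float], events: Sequence[bool],
               group_labels: Sequence, endpoint: str = "OS",
               reference=None) -> SurvivalComparison:
    """Two-group log-rank test with a Mantel-Haenszel hazard ratio.

    Groups are ordered (group1, group2) = ``sorted(set(group_labels))``, or
    with ``reference`` first when given.  The reported hazard ratio is
    HR = (O2/E2)/(O1/E1) — the group2 hazard relative to group1 — with a
    log-scale normal CI using se(log HR) = sqrt(1/E1 + 1/E2).  The p-value is
    the chi-square tail of (O1-E1)^2/V with 1 df, with standard
    hypergeometric tie handling.
    """
    labels = sorted(set(group_labels))
    if len(labels) != 2:
        raise ValidationError(f"km_logrank needs exactly two groups, got {labels}")
    if reference is not None:
        if reference not in labels:
            raise ValidationError(f"reference {reference!r} not among {labels}")
        labels = [reference] + [x for x in labels if x != reference]
    g = np.asarray([1 if x == labels[1] else 0 for x in group_labels])
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) != len(events) or len(times) != len(g):
        raise ValidationError("times, events and group_labels must have equal length")
    o1, e1, o2, e2, v = logrank_table(times, events, g == 1)
    if v > 0:
        chi2 = (o1 - e1) ** 2 / v
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        p = 1.0
    if o1 == 0 or o2 == 0 or e1 == 0 or e2 == 0:
        hr = lo = hi = None
    else:
        hr = (o1 / e1) / (o2 / e2)
        se = math.sqrt(1.0 / e1 + 1.0 / e2)
        lo = hr * math.exp(-1.959963984540054 * se)
        hi = hr * math.exp(1.959963984540054 * se)
    return SurvivalComparison(
        hazard_ratio=hr, hr_ci_low=lo, hr_ci_high=hi, logrank_p=p,
        n_group1=int((g == 0).sum()), n_group2=int((g == 1).sum()),
        endpoint=endpoint, cox_hazard_ratio=_cox_hr(times, events, g))


def _cox_hr(times: np.ndarray, events: np.ndarray, g: np.ndarray) -> float | None:
    """Two-group Cox partial-likelihood hazard ratio (group2 vs group1).

    The O/E log-rank hazard ratio attenuates markedly toward 1 once the true
    ratio is large; the partial-likelihood estimate does not, so it is also
    reported.  Returns None when the fit is degenerate (e.g. a group without
    events, or complete separation).
    """
    import warnings

    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    if (events & (g == 1)).sum() == 0 or (events & (g == 0)).sum() == 0:
        return None
    df = pd.DataFrame({"t": times, "e": events.astype(int), "x": g.astype(int)})
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        return float(math.exp(fit.params_["x"]))
    except (ConvergenceError, ValueError):
        return None


def km_curve(times: Sequence[float], events: Sequence[bool]) -> pd.DataFrame:
    """Kaplan-Meier survival estimate (time, at_risk, events, survival)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    rows = []
    s = 1.0
    for t in np.unique(times[events]):
        n = int((times >= t).sum())
        d = int((events & (times == t)).sum())
        s *= 1.0 - d / n
        rows.append((float(t), n, d, s))
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival"])


def dichotomize_by_median(values: Sequence[float]) -> list[str]:
    """Split at the median: labels "above" (> median) vs "at_or_below".

    Ties at the median fall in the at-or-below (lower-risk) group; an
    all-identical vector admits no split.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValidationError("dichotomize_by_median needs at least two values")
    if np.all(v == v[0]):
        raise UndefinedResultError("all values identical: no median split exists")
    med = float(np.median(v))
    return ["above" if x > med else "at_or_below" for x in v]


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> AssociationResult:
    """Spearman rank correlation with average ranks for ties (two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must be paired")
    if len(x) < 3:
        raise ValidationError("spearman_corr needs n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedResultError("constant vector: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return AssociationResult(statistic=float(rho), p_value=float(p), n=len(x),
                             kind="spearman")


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> AssociationResult:
    """Two-sided Mann-Whitney U; exact null for combined n <= 20 without ties."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("mann_whitney needs non-empty groups")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return AssociationResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                             n=len(a) + len(b), kind="mann_whitney")


def penetration_rate(csf_nM: float, plasma_nM: float) -> float:
    """CSF drug concentration as a percentage of the plasma concentration."""
    if plasma_nM is None or plasma_nM <= 0:
        raise UndefinedResultError("penetration rate undefined for plasma_nM <= 0")
    return 100.0 * csf_nM / plasma_nM


def vaf_percent_change(pre_vaf: float, post_vaf: float) -> float:
    """Percent change in VAF between serial samples: 100 * (post - pre) / pre."""
    if pre_vaf <= 0:
        if post_vaf > 0:
            raise UndefinedResultError("new detection: percent change undefined "
                                       "(pre-treatment VAF was zero)")
        raise UndefinedResultError("percent change undefined for pre_vaf <= 0")
    return 100.0 * (post_vaf - pre_vaf) / pre_vaf
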