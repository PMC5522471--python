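"""Threshold classification of indices and diagnostic-performance evaluation.

A nodule is called *suspicious* when its index value is at or above the
method's cutoff (boundary inclusive): WOind ≥ −19 % or R.I. ≥ −11.94.
Histology is the ground truth, with differentiated thyroid cancer (DTC) the
positive class.  Performance is summarized by the 2×2 confusion counts and
sensitivity, specificity, accuracy, PPV and NPV (percent), each with an
exact Clopper–Pearson 95 % interval; a metric whose denominator is zero is
reported as absent with a reason, never as 0.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .indices import IndexMethod, IndexResult
from .study_io import Histology, PatientRecord, Sex, load_cohort_table

__all__ = [
    "Call",
    "DecisionThresholds",
    "Decision",
    "ConfusionCounts",
    "MetricEstimate",
    "PerformanceReport",
    "classify",
    "classify_value",
    "decisions_from_records",
    "evaluate",
    "agreement",
    "cutoff_sweep",
    "cohort_demographics",
    "analyze_reference_cohort",
]

DEFAULT_WOIND_CUTOFF = -19.0
DEFAULT_RI_CUTOFF = -11.94


class Call(str, enum.Enum):
    SUSPICIOUS = "suspicious"
    BENIGN = "benign"


@dataclass(frozen=True)
class DecisionThresholds:
    """Published decision cutoffs; values at or above a cutoff are suspicious."""

    woind_cutoff_percent: float = DEFAULT_WOIND_CUTOFF
    ri_cutoff: float = DEFAULT_RI_CUTOFF

    def cutoff_for(self, method: IndexMethod) -> float:
        return (
            self.woind_cutoff_percent
            if method is IndexMethod.WOIND
            else self.ri_cutoff
        )


@dataclass(frozen=True)
class Decision:
    patient_id: object
    method: IndexMethod
    call: Call
    index_value: float


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricEstimate:
    """A percentage with its exact binomial 95 % CI, or an absence reason."""

    value: Optional[float]
    ci_95: Optional[tuple[float, float]]
    numerator: int
    denominator: int
    undefined_reason: Optional[str] = None


@dataclass(frozen=True)
class PerformanceReport:
    method: Optional[IndexMethod]
    counts: ConfusionCounts
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    accuracy: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate

    def to_dict(self) -> dict:
        def metric(m: MetricEstimate) -> dict:
            return {
                "value": m.value,
                "ci_95": list(m.ci_95) if m.ci_95 else None,
                "numerator": m.numerator,
                "denominator": m.denominator,
                "undefined_reason": m.undefined_reason,
            }

        return {
            "method": self.method.value if self.method else None,
            "counts": {
                "tp": self.counts.tp,
                "fp": self.counts.fp,
                "tn": self.counts.tn,
                "fn": self.counts.fn,
            },
            "sensitivity": metric(self.sensitivity),
            "specificity": metric(self.specificity),
            "accuracy": metric(self.accuracy),
            "ppv": metric(self.ppv),
            "npv": metric(self.npv),
        }


def classify_value(
    method: IndexMethod, value: float, thresholds: DecisionThresholds | None = None
) -> Call:
    """Suspicious iff ``value >= cutoff`` for the method (boundary inclusive)."""
    thresholds = thresholds or DecisionThresholds()
    if not np.isfinite(value):
        raise ValueError(f"index value must be finite, got {value!r}")
    return Call.SUSPICIOUS if value >= thresholds.cutoff_for(method) else Call.BENIGN


def classify(
    index: IndexResult,
    thresholds: DecisionThresholds | None = None,
    patient_id: object = None,
) -> Decision:
    """Threshold one computed index into a suspicious/benign call."""
    call = classify_value(index.method, index.value, thresholds)
    return Decision(
        patient_id=patient_id, method=index.method, call=call, index_value=index.value
    )


def decisions_from_records(
    records: Sequence[PatientRecord],
    method: IndexMethod,
    thresholds: DecisionThresholds | None = None,
) -> list[Decision]:
    """Classify the index values printed in a cohort table."""
    out = []
    for rec in records:
        value = rec.woind_percent if method is IndexMethod.WOIND else rec.ri
        call = classify_value(method, value, thresholds)
        out.append(
            Decision(
                patient_id=rec.patient_id, method=method, call=call, index_value=value
            )
        )
    return out


def _metric(numerator: int, denominator: int, what: str) -> MetricEstimate:
    if denominator == 0:
        return MetricEstimate(
            value=None,
            ci_95=None,
            numerator=numerator,
            denominator=denominator,
            undefined_reason=f"no {what} in the evaluated set",
        )
    lo, hi = proportion_confint(numerator, denominator, alpha=0.05, method="beta")
    return MetricEstimate(
        value=100.0 * numerator / denominator,
        ci_95=(100.0 * float(lo), 100.0 * float(hi)),
        numerator=numerator,
        denominator=denominator,
    )


def evaluate(
    decisions: Sequence[Decision], records: Sequence[PatientRecord]
) -> PerformanceReport:
    """Confusion counts and diagnostic metrics of decisions against histology.

    Decisions and records are matched by ``patient_id`` (exactly one decision
    per record); truth is malignant ⇔ histology DTC.
    """
    truth = {rec.patient_id: rec.is_malignant for rec in records}
    if len(truth) != len(records):
        raise ValueError("duplicate patient_id in records")
    seen = set()
    tp = fp = tn = fn = 0
    for d in decisions:
        if d.patient_id not in truth:
            raise ValueError(f"decision for unknown patient_id {d.patient_id!r}")
        if d.patient_id in seen:
            raise ValueError(f"duplicate decision for patient_id {d.patient_id!r}")
        seen.add(d.patient_id)
        malignant = truth[d.patient_id]
        positive = d.call is Call.SUSPICIOUS
        if positive and malignant:
            tp += 1
        elif positive and not malignant:
            fp += 1
        elif not positive and malignant:
            fn += 1
        else:
            tn += 1
    if seen != set(truth):
        missing = sorted(set(truth) - seen)
        raise ValueError(f"no decision for patient_id(s) {missing}")

    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    methods = {d.method for d in decisions}
    return PerformanceReport(
        method=methods.pop() if len(methods) == 1 else None,
        counts=counts,
        sensitivity=_metric(tp, tp + fn, "malignant patients"),
        specificity=_metric(tn, tn + fp, "benign patients"),
        accuracy=_metric(tp + tn, counts.total, "patients"),
        ppv=_metric(tp, tp + fp, "suspicious calls"),
        npv=_metric(tn, tn + fn, "benign calls"),
    )


def agreement(
    decisions_a: Sequence[Decision], decisions_b: Sequence[Decision]
) -> float:
    """Percent of patients on whom two decision sets make the same call."""
    a = {d.patient_id: d.call for d in decisions_a}
    b = {d.patient_id: d.call for d in decisions_b}
    if len(a) != len(decisions_a) or len(b) != len(decisions_b):
        raise ValueError("duplicate patient_id within a decision set")
    if a.keys() != b.keys():
        raise ValueError("decision sets cover different patients")
    if not a:
        raise ValueError("empty decision sets")
    concordant = sum(1 for pid in a if a[pid] == b[pid])
    return 100.0 * concordant / len(a)


def cutoff_sweep(
    records: Sequence[PatientRecord],
    method: IndexMethod,
    cutoffs: Iterable[float],
) -> list[tuple[float, PerformanceReport]]:
    """Performance across a grid of cutoffs (diagnostic utility, not a fit)."""
    out = []
    for cut in cutoffs:
        thr = (
            DecisionThresholds(woind_cutoff_percent=cut)
            if method is IndexMethod.WOIND
            else DecisionThresholds(ri_cutoff=cut)
        )
        out.append((cut, evaluate(decisions_from_records(records, method, thr), records)))
    return out


def cohort_demographics(records: Sequence[PatientRecord]) -> dict:
    """Descriptive statistics of a cohort table."""
    ages = np.array([r.age_years for r in records], dtype=float)
    n_mal = sum(r.is_malignant for r in records)
    return {
        "n_patients": len(records),
        "n_female": sum(r.sex is Sex.F for r in records),
        "n_male": sum(r.sex is Sex.M for r in records),
        "age_mean": float(ages.mean()),
        "age_median": float(np.median(ages)),
        "age_min": int(ages.min()),
        "age_max": int(ages.max()),
        "n_malignant": int(n_mal),
        "malignant_percent": 100.0 * n_mal / len(records),
        "histology_counts": {
            h.value: sum(r.histology is h for r in records) for h in Histology
        },
    }


_RI_DISCREPANCY_NOTE = (
    "The originally reported R.I. specificity (57.1%) and accuracy (62.5%) are "
    "not reproducible from the per-patient table: under the cutoff R.I. >= "
    "-11.94 the 16 benign nodules split 4 TN / 12 FP, giving specificity 25% "
    "and accuracy 40%, consistent with the reported PPV 25%, NPV 100%, 12 "
    "false positives and 4 R.I.-benign patients. This package reports the "
    "table-consistent values."
)


def analyze_reference_cohort(
    thresholds: DecisionThresholds | None = None,
) -> dict:
    """Full evaluation of the packaged 20-patient reference cohort.

    Classifies the printed WOind and R.I. values of every patient, evaluates
    both methods against histology, and computes their inter-method
    agreement and the cohort demographics.  The returned dictionary is the
    payload of the ``reference-cohort`` CLI subcommand.
    """
    thresholds = thresholds or DecisionThresholds()
    records = load_cohort_table()
    d_wo = decisions_from_records(records, IndexMethod.WOIND, thresholds)
    d_ri = decisions_from_records(records, IndexMethod.RI, thresholds)
    return {
        "thresholds": {
            "woind_cutoff_percent": thresholds.woind_cutoff_percent,
            "ri_cutoff": thresholds.ri_cutoff,
        },
        "demographics": cohort_demographics(records),
        "woind": evaluate(d_wo, records).to_dict(),
        "ri": evaluate(d_ri, records).to_dict(),
        "agreement_percent": agreement(d_wo, d_ri),
        "decisions": {
            "woind": {d.patient_id: d.call.value for d in d_wo},
            "ri": {d.patient_id: d.call.value for d in d_ri},
        },
        "notes": [_RI_DISCREPANCY_NOTE],
    }
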