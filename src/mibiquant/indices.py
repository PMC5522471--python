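"""The two competing quantitative indices for dual-time-point MIBI scans.

Wash-out index (WOind)
    Percent change of the background-subtracted mean nodular count between
    the early (+10 min) and late (+60 min) frames.  With ``ER = mean_nodule -
    mean_background`` on the early frame and ``LR`` the same difference on
    the late frame::

        WOind = 100 * LR / ER - 100

    The background here is the nodule ROI mirrored *outside* the thyroid, so
    the index tracks nodular kinetics alone.  A negative WOind means the
    nodule washes tracer out (early uptake > late uptake).

Retention index (R.I.)
    Percent change of the nodule-to-normal-tissue uptake ratio.  The normal
    tissue is the nodule ROI mirrored onto the contralateral lobe, and both
    numerator and denominator are corrected for body background measured in
    a thoracic ROI::

        ER = (mean_nodule_early - mean_thorax_early) / (mean_contra_early - mean_thorax_early)
        DR = (mean_nodule_late  - mean_thorax_late)  / (mean_contra_late  - mean_thorax_late)
        R.I. = 100 * (DR - ER) / ER

    A positive R.I. means nodule-to-normal contrast rises from early to late.
    Because normal parenchyma clears MIBI faster than nodules do, R.I. rises
    for benign adenomas too — the behaviour behind its false positives.

Both functions work on per-pixel mean counts (never totals), take their
timepoints from the measurement metadata, and optionally decay-correct the
means first.  R.I. is exactly invariant to decay correction (the common
same-timepoint factor cancels); WOind shifts by ``2**((t_late - t_early) /
T_half)`` on the ``LR/ER`` ratio.
"""

from __future__ import annotations

import enum
import hashlib
from dataclasses import dataclass
from typing import Optional

from .roi_quant import DecaySpec, RoiStats, copy_roi_to_late, decay_correct, roi_mean_counts
from .study_io import RoiLabel, StudyBundle

__all__ = [
    "IndexMethod",
    "IndexResult",
    "NonPositiveNetUptakeError",
    "DegenerateRatioError",
    "washout_index",
    "retention_index",
    "quantify_study",
]


class IndexMethod(str, enum.Enum):
    WOIND = "WOind"
    RI = "RI"


class NonPositiveNetUptakeError(ValueError):
    """Early nodular counts do not exceed background: no quantifiable uptake."""


class DegenerateRatioError(ValueError):
    """A ratio denominator (normal tissue minus background) is non-positive."""


@dataclass(frozen=True)
class IndexResult:
    """One computed index with its intermediates, on the percent scale.

    ``late_term`` is LR for the wash-out index and DR for the retention
    index.  ``flags`` carries non-fatal conditions such as a late nodular
    count below background (WOind < −100).
    """

    method: IndexMethod
    value: float
    er: float
    late_term: float
    decay_corrected: bool
    inputs_digest: str
    flags: tuple = ()

    def to_dict(self, patient_id: Optional[object] = None) -> dict:
        out = {
            "method": self.method.value,
            "value": self.value,
            "ER": self.er,
            "late_term": self.late_term,
            "decay_corrected": self.decay_corrected,
            "flags": list(self.flags),
        }
        if patient_id is not None:
            out = {"patient_id": patient_id, **out}
        return out


def _digest(*stats: RoiStats) -> str:
    payload = "|".join(
        f"{s.label.value}:{s.t_acq_min}:{s.mean_counts_per_pixel}:{s.n_pixels}"
        for s in stats
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _require(stats: RoiStats, label: RoiLabel, role: str) -> None:
    if stats.label is not label:
        raise ValueError(f"{role} statistics carry label {stats.label.value!r}, expected {label.value!r}")


def _maybe_correct(stats: RoiStats, decay: DecaySpec) -> RoiStats:
    return decay_correct(stats, decay) if decay.enabled else stats


def washout_index(
    nodule_early: RoiStats,
    bkg_early: RoiStats,
    nodule_late: RoiStats,
    bkg_late: RoiStats,
    decay: DecaySpec = DecaySpec(),
) -> IndexResult:
    """Wash-out index from nodule and mirrored-background ROI statistics.

    Raises :class:`NonPositiveNetUptakeError` when the early net uptake
    ``ER`` is not positive (the nodule cannot be distinguished from
    background).  A negative late net uptake is allowed — the index drops
    below −100 — and is flagged ``late_below_background``.
    """
    _require(nodule_early, RoiLabel.NODULE, "nodule_early")
    _require(nodule_late, RoiLabel.NODULE, "nodule_late")
    _require(bkg_early, RoiLabel.MIRROR_BACKGROUND, "bkg_early")
    _require(bkg_late, RoiLabel.MIRROR_BACKGROUND, "bkg_late")
    if nodule_early.t_acq_min != bkg_early.t_acq_min:
        raise ValueError("early nodule and background frames have different times")
    if nodule_late.t_acq_min != bkg_late.t_acq_min:
        raise ValueError("late nodule and background frames have different times")
    if nodule_early.t_acq_min >= nodule_late.t_acq_min:
        raise ValueError("early frame must precede late frame")

    digest = _digest(nodule_early, bkg_early, nodule_late, bkg_late)
    ne, be, nl, bl = (
        _maybe_correct(s, decay)
        for s in (nodule_early, bkg_early, nodule_late, bkg_late)
    )
    er = ne.mean_counts_per_pixel - be.mean_counts_per_pixel
    lr = nl.mean_counts_per_pixel - bl.mean_counts_per_pixel
    if er <= 0:
        raise NonPositiveNetUptakeError(
            f"early net nodular uptake ER = {er:.6g} <= 0; nodule not "
            "distinguishable from background"
        )
    flags = ("late_below_background",) if lr < 0 else ()
    value = 100.0 * lr / er - 100.0
    return IndexResult(
        method=IndexMethod.WOIND,
        value=value,
        er=er,
        late_term=lr,
        decay_corrected=decay.enabled,
        inputs_digest=digest,
        flags=flags,
    )


def retention_index(
    nodule_early: RoiStats,
    contralateral_early: RoiStats,
    thorax_bkg_early: RoiStats,
    nodule_late: RoiStats,
    contralateral_late: RoiStats,
    thorax_bkg_late: RoiStats,
    decay: DecaySpec = DecaySpec(),
) -> IndexResult:
    """Retention index from nodule, contralateral-lobe and thorax ROI statistics.

    Raises :class:`DegenerateRatioError` when a background-subtracted
    denominator or the early ratio is not positive.
    """
    _require(nodule_early, RoiLabel.NODULE, "nodule_early")
    _require(nodule_late, RoiLabel.NODULE, "nodule_late")
    _require(contralateral_early, RoiLabel.CONTRALATERAL, "contralateral_early")
    _require(contralateral_late, RoiLabel.CONTRALATERAL, "contralateral_late")
    _require(thorax_bkg_early, RoiLabel.THORAX_BACKGROUND, "thorax_bkg_early")
    _require(thorax_bkg_late, RoiLabel.THORAX_BACKGROUND, "thorax_bkg_late")
    for a, b in ((nodule_early, contralateral_early), (nodule_early, thorax_bkg_early)):
        if a.t_acq_min != b.t_acq_min:
            raise ValueError("early-frame ROI statistics have inconsistent times")
    for a, b in ((nodule_late, contralateral_late), (nodule_late, thorax_bkg_late)):
        if a.t_acq_min != b.t_acq_min:
            raise ValueError("late-frame ROI statistics have inconsistent times")
    if nodule_early.t_acq_min >= nodule_late.t_acq_min:
        raise ValueError("early frame must precede late frame")

    digest = _digest(
        nodule_early, contralateral_early, thorax_bkg_early,
        nodule_late, contralateral_late, thorax_bkg_late,
    )
    ne, ce, te, nl, cl, tl = (
        _maybe_correct(s, decay)
        for s in (
            nodule_early, contralateral_early, thorax_bkg_early,
            nodule_late, contralateral_late, thorax_bkg_late,
        )
    )
    den_e = ce.mean_counts_per_pixel - te.mean_counts_per_pixel
    den_l = cl.mean_counts_per_pixel - tl.mean_counts_per_pixel
    if den_e <= 0 or den_l <= 0:
        raise DegenerateRatioError(
            "normal-tissue counts do not exceed thorax background "
            f"(early {den_e:.6g}, late {den_l:.6g})"
        )
    er = (ne.mean_counts_per_pixel - te.mean_counts_per_pixel) / den_e
    dr = (nl.mean_counts_per_pixel - tl.mean_counts_per_pixel) / den_l
    if er <= 0:
        raise DegenerateRatioError(f"early nodule-to-normal ratio ER = {er:.6g} <= 0")
    value = 100.0 * (dr - er) / er
    return IndexResult(
        method=IndexMethod.RI,
        value=value,
        er=er,
        late_term=dr,
        decay_corrected=decay.enabled,
        inputs_digest=digest,
    )


def quantify_study(
    study: StudyBundle,
    decay: DecaySpec = DecaySpec(),
    copy_scale: float | None = None,
) -> tuple[IndexResult, IndexResult]:
    """Compute both indices for one dual-time-point study.

    ROIs are drawn on the early frame and copied onto the late one (with an
    explicit ``copy_scale`` when the matrices differ).  Requires the nodule
    and mirror-background ROIs for WOind and additionally the contralateral
    and thorax-background ROIs for R.I.; a missing label is reported by name.
    Returns ``(woind_result, ri_result)``; the intermediate per-ROI
    statistics are recoverable through :func:`mibiquant.roi_quant.roi_mean_counts`.
    """
    needed = (
        RoiLabel.NODULE,
        RoiLabel.MIRROR_BACKGROUND,
        RoiLabel.CONTRALATERAL,
        RoiLabel.THORAX_BACKGROUND,
    )
    missing = [label.value for label in needed if label not in study.rois]
    if missing:
        raise ValueError(f"study lacks required ROI(s): {', '.join(missing)}")

    early_stats: dict[RoiLabel, RoiStats] = {}
    late_stats: dict[RoiLabel, RoiStats] = {}
    for label in needed:
        roi = study.rois[label]
        early_stats[label] = roi_mean_counts(study.early, roi)
        late_roi = copy_roi_to_late(
            roi, study.early.matrix_size, study.late.matrix_size, scale=copy_scale
        )
        late_stats[label] = roi_mean_counts(study.late, late_roi)

    wo = washout_index(
        early_stats[RoiLabel.NODULE],
        early_stats[RoiLabel.MIRROR_BACKGROUND],
        late_stats[RoiLabel.NODULE],
        late_stats[RoiLabel.MIRROR_BACKGROUND],
        decay=decay,
    )
    ri = retention_index(
        early_stats[RoiLabel.NODULE],
        early_stats[RoiLabel.CONTRALATERAL],
        early_stats[RoiLabel.THORAX_BACKGROUND],
        late_stats[RoiLabel.NODULE],
        late_stats[RoiLabel.CONTRALATERAL],
        late_stats[RoiLabel.THORAX_BACKGROUND],
        decay=decay,
    )
    return wo, ri
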