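"""Synthetic dual-time-point MIBI studies with known kinetic ground truth.

No public image archive exists for quantitative MIBI thyroid scintigraphy,
so this module generates the inputs the pipeline needs: a two-lobe thyroid
phantom with a cold-on-pertechnetate, MIBI-avid nodule, imaged at two
timepoints with Poisson counting noise, plus the closed-form index values
the noiseless pipeline must reproduce.

Kinetic model
-------------
Each compartment (nodule, parenchyma, body background) has a count-rate
density ``a0`` (counts · pixel⁻¹ · s⁻¹ at injection time) and a retention
factor ``f`` in (0, 1]: the fraction of its early-frame rate still present
at the late frame.  This is the single-exponential wash-out over the
early→late window collapsed to one number per compartment.  Normal
parenchyma clears MIBI faster than nodules (benign or malignant), so
``f_parenchyma < f_nodule`` is enforced by default; malignant nodules
retain more than benign ones.  Physical isotope decay can be layered on
top (``apply_physical_decay``) as a common ``2**(-t/T_half)`` factor.

With the default benign kinetics the analytic wash-out index is −30 % and
the malignant default gives ≈ −8 %, straddling the −19 % decision cutoff;
both classes sit well above the R.I. cutoff, mirroring the retention
index's false-positive behaviour on benign adenomas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats as _sstats

from .indices import (
    DegenerateRatioError,
    IndexMethod,
    NonPositiveNetUptakeError,
)
from .roi_quant import TC99M_HALF_LIFE_MIN, mirror_roi
from .study_io import PlanarImage, RoiLabel, RoiMask, StudyBundle, Tracer

__all__ = [
    "PhantomGeometryError",
    "PhantomGeometry",
    "KineticParams",
    "CohortSimConfig",
    "PhantomStudy",
    "SimulatedPatient",
    "build_phantom",
    "analytic_index",
    "simulate_cohort",
]


class PhantomGeometryError(ValueError):
    """The requested phantom violates a geometric invariant."""


@dataclass(frozen=True)
class PhantomGeometry:
    """Two-lobe thyroid with an isthmus and one nodule, on a square matrix.

    Lobes are ellipses placed symmetrically about the vertical midline; the
    nodule is a disc inside one lobe whose radius follows from its physical
    size and the pixel pitch.  The thorax-background ROI is a rectangle
    below the gland.  All lengths are pixels unless suffixed ``_mm``.
    """

    grid: tuple[int, int] = (256, 256)
    pixel_size_mm: float = 1.5
    lobe_center_row: float = 128.0
    lobe_col_offset: float = 35.5
    lobe_semi_axes: tuple[float, float] = (30.0, 14.0)  # (row, col) semi-axes
    isthmus_rows: tuple[int, int] = (140, 154)
    nodule_center: tuple[float, float] = (140.0, 92.0)
    nodule_size_mm: float = 25.0
    thorax_rect: tuple[int, int, int, int] = (205, 235, 25, 60)  # r0, r1, c0, c1

    @property
    def midline_col(self) -> float:
        return (self.grid[1] - 1) / 2.0

    @property
    def nodule_radius_px(self) -> float:
        return self.nodule_size_mm / (2.0 * self.pixel_size_mm)

    def _ellipse_mask(self, center_col: float) -> np.ndarray:
        rows, cols = self.grid
        rr, cc = np.mgrid[0:rows, 0:cols]
        ar, ac = self.lobe_semi_axes
        return (
            ((rr - self.lobe_center_row) / ar) ** 2
            + ((cc - center_col) / ac) ** 2
        ) <= 1.0

    def masks(self) -> dict[str, np.ndarray]:
        """Boolean compartment masks: left/right lobe, isthmus, nodule, thyroid."""
        rows, cols = self.grid
        left = self._ellipse_mask(self.midline_col - self.lobe_col_offset)
        right = self._ellipse_mask(self.midline_col + self.lobe_col_offset)
        rr, cc = np.mgrid[0:rows, 0:cols]
        r0, r1 = self.isthmus_rows
        isthmus = (
            (rr >= r0)
            & (rr <= r1)
            & (cc >= self.midline_col - self.lobe_col_offset)
            & (cc <= self.midline_col + self.lobe_col_offset)
        )
        nr, nc = self.nodule_center
        nodule = ((rr - nr) ** 2 + (cc - nc) ** 2) <= self.nodule_radius_px**2
        thyroid = left | right | isthmus
        return {
            "left_lobe": left,
            "right_lobe": right,
            "isthmus": isthmus,
            "nodule": nodule,
            "thyroid": thyroid,
        }

    def validate(self) -> dict[str, np.ndarray]:
        m = self.masks()
        if np.any(m["left_lobe"] & m["right_lobe"]):
            raise PhantomGeometryError("lobes overlap")
        in_left = np.array_equal(m["nodule"] & m["left_lobe"], m["nodule"])
        in_right = np.array_equal(m["nodule"] & m["right_lobe"], m["nodule"])
        if not (in_left or in_right):
            raise PhantomGeometryError("nodule disc is not contained in one lobe")
        if not np.any(m["nodule"]):
            raise PhantomGeometryError("nodule disc covers no pixel")
        r0, r1, c0, c1 = self.thorax_rect
        rows, cols = self.grid
        if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
            raise PhantomGeometryError("thorax rectangle outside the grid")
        thorax = np.zeros(self.grid, dtype=bool)
        thorax[r0:r1, c0:c1] = True
        if np.any(thorax & m["thyroid"]):
            raise PhantomGeometryError("thorax rectangle intersects the thyroid")
        m["thorax"] = thorax
        m["nodule_side"] = "left" if in_left else "right"  # type: ignore[assignment]
        return m


@dataclass(frozen=True)
class KineticParams:
    """Per-compartment count-rate densities and early→late retention factors."""

    a0_nodule: float = 0.20
    a0_parenchyma: float = 0.12
    a0_body_background: float = 0.02
    f_nodule: float = 0.70
    f_parenchyma: float = 0.50
    f_background: float = 0.70
    apply_physical_decay: bool = False
    half_life_min: float = TC99M_HALF_LIFE_MIN
    require_parenchyma_faster: bool = True

    def __post_init__(self) -> None:
        for name in ("a0_nodule", "a0_parenchyma", "a0_body_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("f_nodule", "f_parenchyma", "f_background"):
            f = getattr(self, name)
            if not (0.0 < f <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {f}")
        if self.half_life_min <= 0:
            raise ValueError("half_life_min must be positive")
        if self.require_parenchyma_faster and not (self.f_parenchyma < self.f_nodule):
            raise ValueError(
                "parenchyma must clear faster than the nodule "
                f"(f_parenchyma={self.f_parenchyma} >= f_nodule={self.f_nodule}); "
                "set require_parenchyma_faster=False to override"
            )


@dataclass(frozen=True)
class PhantomStudy:
    """One simulated patient: images + truth ROIs + the generating kinetics."""

    study: StudyBundle
    geometry: PhantomGeometry
    kinetics: KineticParams
    early_intensity: np.ndarray
    late_intensity: np.ndarray
    seed: Optional[int]

    @property
    def truth_rois(self) -> dict[RoiLabel, RoiMask]:
        return dict(self.study.rois)


def _decay_factor(kinetics: KineticParams, t_min: float) -> float:
    if not kinetics.apply_physical_decay:
        return 1.0
    return 2.0 ** (-t_min / kinetics.half_life_min)


def _mirror_background_axis(
    geometry: PhantomGeometry, masks: dict[str, np.ndarray]
) -> float:
    """Axis that reflects the nodule into clear background lateral to the gland."""
    thyroid_cols = np.nonzero(masks["thyroid"].any(axis=0))[0]
    if masks["nodule_side"] == "left":
        clear_center = thyroid_cols.min() / 2.0
    else:
        clear_center = (thyroid_cols.max() + geometry.grid[1] - 1) / 2.0
    # place the reflected disc at the centre of the clear lateral zone
    return round((geometry.nodule_center[1] + clear_center)) / 2.0


def build_phantom(
    geometry: PhantomGeometry | None = None,
    kinetics: KineticParams | None = None,
    times: tuple[float, float] = (10.0, 60.0),
    frame_s: float = 600.0,
    noise: str = "poisson",
    seed: Optional[int] = None,
) -> PhantomStudy:
    """Simulate one dual-time-point study with truth ROIs.

    Early pixel intensity is ``a0 * frame_s`` for the pixel's compartment
    (times the physical-decay factor when enabled); the late frame scales
    each compartment by its retention factor.  ``noise="poisson"`` draws
    independent per-pixel Poisson counts (a ``seed`` is then required);
    ``noise="none"`` emits the exact real-valued intensities so the pipeline
    can be checked against the closed form.

    The four truth ROIs are the nodule disc, its mirror onto the
    contralateral lobe (about the gland midline), its mirror into clear
    background lateral to the gland, and the thorax rectangle.
    """
    geometry = geometry or PhantomGeometry()
    kinetics = kinetics or KineticParams()
    t_early, t_late = times
    if not (0 <= t_early < t_late):
        raise ValueError(f"need 0 <= t_early < t_late, got {times}")
    if noise not in ("poisson", "none"):
        raise ValueError(f"noise must be 'poisson' or 'none', got {noise!r}")
    if noise == "poisson" and seed is None:
        raise ValueError("a seed is required for Poisson noise")

    masks = geometry.validate()
    parenchyma = masks["thyroid"] & ~masks["nodule"]

    a0 = np.full(geometry.grid, kinetics.a0_body_background, dtype=float)
    a0[parenchyma] = kinetics.a0_parenchyma
    a0[masks["nodule"]] = kinetics.a0_nodule
    f = np.full(geometry.grid, kinetics.f_background, dtype=float)
    f[parenchyma] = kinetics.f_parenchyma
    f[masks["nodule"]] = kinetics.f_nodule

    early_intensity = a0 * frame_s * _decay_factor(kinetics, t_early)
    late_intensity = a0 * f * frame_s * _decay_factor(kinetics, t_late)

    if noise == "poisson":
        rng = np.random.default_rng(seed)
        early_counts = rng.poisson(early_intensity).astype(np.int64)
        late_counts = rng.poisson(late_intensity).astype(np.int64)
    else:
        early_counts = early_intensity
        late_counts = late_intensity

    nodule_roi = RoiMask.from_mask_array(masks["nodule"], RoiLabel.NODULE)
    contralateral = mirror_roi(nodule_roi, geometry.midline_col, RoiLabel.CONTRALATERAL)
    contra_lobe = masks["right_lobe" if masks["nodule_side"] == "left" else "left_lobe"]
    contra_ok = all(contra_lobe[r, c] for r, c in contralateral.pixels)
    if not contra_ok:
        raise PhantomGeometryError(
            "mirrored contralateral ROI is not contained in the opposite lobe"
        )
    bg_axis = _mirror_background_axis(geometry, masks)
    mirror_bg = mirror_roi(nodule_roi, bg_axis, RoiLabel.MIRROR_BACKGROUND)
    if any(masks["thyroid"][r, c] for r, c in mirror_bg.pixels):
        raise PhantomGeometryError("mirrored background ROI intersects the thyroid")
    thorax_roi = RoiMask.from_mask_array(masks["thorax"], RoiLabel.THORAX_BACKGROUND)

    def _frame(counts: np.ndarray, t: float) -> PlanarImage:
        return PlanarImage(
            counts=counts,
            t_acq_min=t,
            frame_duration_s=frame_s,
            tracer=Tracer.MIBI,
        )

    study = StudyBundle(
        early=_frame(early_counts, t_early),
        late=_frame(late_counts, t_late),
        rois={
            RoiLabel.NODULE: nodule_roi,
            RoiLabel.MIRROR_BACKGROUND: mirror_bg,
            RoiLabel.CONTRALATERAL: contralateral,
            RoiLabel.THORAX_BACKGROUND: thorax_roi,
        },
    )
    return PhantomStudy(
        study=study,
        geometry=geometry,
        kinetics=kinetics,
        early_intensity=early_intensity,
        late_intensity=late_intensity,
        seed=seed,
    )


def analytic_index(
    kinetics: KineticParams,
    method: IndexMethod,
    times: tuple[float, float] = (10.0, 60.0),
) -> float:
    """Closed-form noiseless index value for the phantom kinetics.

    The wash-out index sees the body background through the mirrored ROI::

        WOind = 100 * (a0_n f_n - a0_bg f_bg) / (a0_n - a0_bg) * D - 100

    with ``D = 2**(-(t_late - t_early)/T_half)`` when physical decay is
    simulated and left uncorrected, else 1.  The retention index uses the
    parenchyma as normal tissue and is decay-free by cancellation::

        ER = (a0_n - a0_bg) / (a0_p - a0_bg)
        DR = (a0_n f_n - a0_bg f_bg) / (a0_p f_p - a0_bg f_bg)
        R.I. = 100 * (DR - ER) / ER
    """
    k = kinetics
    t_early, t_late = times
    method = IndexMethod(method)
    if method is IndexMethod.WOIND:
        er = k.a0_nodule - k.a0_body_background
        if er <= 0:
            raise NonPositiveNetUptakeError(
                "nodule rate does not exceed background rate"
            )
        lr = k.a0_nodule * k.f_nodule - k.a0_body_background * k.f_background
        decay_ratio = _decay_factor(k, t_late) / _decay_factor(k, t_early)
        return 100.0 * (lr / er) * decay_ratio - 100.0
    den_e = k.a0_parenchyma - k.a0_body_background
    den_l = k.a0_parenchyma * k.f_parenchyma - k.a0_body_background * k.f_background
    if den_e <= 0 or den_l <= 0:
        raise DegenerateRatioError("parenchyma rate does not exceed background rate")
    er = (k.a0_nodule - k.a0_body_background) / den_e
    dr = (k.a0_nodule * k.f_nodule - k.a0_body_background * k.f_background) / den_l
    if er <= 0:
        raise DegenerateRatioError("early nodule-to-normal ratio is not positive")
    return 100.0 * (dr - er) / er


@dataclass(frozen=True)
class CohortSimConfig:
    """Cohort-level simulation: class mix and kinetic-parameter distributions.

    Nodule and parenchyma retention factors are drawn from truncated normal
    distributions (support (0, 1]); benign nodules retain a mean 0.70 of
    their early rate, malignant 0.90, parenchyma 0.50, each with sd 0.05.
    The malignant fraction defaults to the 20 % prevalence of the reference
    cohort; the number of malignant patients is fixed by deterministic
    rounding of ``n_patients * malignant_fraction``.
    """

    n_patients: int = 20
    malignant_fraction: float = 0.2
    benign_retention_mean: float = 0.70
    malignant_retention_mean: float = 0.90
    parenchyma_retention_mean: float = 0.50
    retention_sd: float = 0.05
    background_retention: float = 0.70
    count_scale: float = 1.0
    noise: str = "poisson"
    times: tuple[float, float] = (10.0, 60.0)
    frame_s: float = 600.0
    apply_physical_decay: bool = False
    seed: int = 0
    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (0.0 <= self.malignant_fraction <= 1.0):
            raise ValueError("malignant_fraction must lie in [0, 1]")
        if self.retention_sd <= 0:
            raise ValueError("retention_sd must be positive")
        if self.count_scale <= 0:
            raise ValueError("count_scale must be positive")
        for name in (
            "benign_retention_mean",
            "malignant_retention_mean",
            "parenchyma_retention_mean",
            "background_retention",
        ):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")


@dataclass(frozen=True)
class SimulatedPatient:
    patient_id: int
    phantom: PhantomStudy
    malignant: bool
    kinetics: KineticParams


def _draw_retention(rng: np.random.Generator, mean: float, sd: float) -> float:
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return float(_sstats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def simulate_cohort(config: CohortSimConfig | None = None) -> list[SimulatedPatient]:
    """Simulate a cohort of dual-time-point studies with known truth labels.

    Fully reproducible under a fixed ``config.seed``: one generator drives
    the label permutation, the kinetic draws and the per-patient Poisson
    seeds.  Within each patient the parenchyma is redrawn until it clears
    faster than the nodule, honouring the kinetic ordering.
    """
    config = config or CohortSimConfig()
    rng = np.random.default_rng(config.seed)
    n_mal = int(round(config.n_patients * config.malignant_fraction))
    labels = np.array([True] * n_mal + [False] * (config.n_patients - n_mal))
    labels = labels[rng.permutation(config.n_patients)]

    base = KineticParams()
    patients: list[SimulatedPatient] = []
    for idx, malignant in enumerate(labels, start=1):
        mean = (
            config.malignant_retention_mean
            if malignant
            else config.benign_retention_mean
        )
        f_nodule = _draw_retention(rng, mean, config.retention_sd)
        f_par = _draw_retention(rng, config.parenchyma_retention_mean, config.retention_sd)
        for _ in range(1000):
            if f_par < f_nodule:
                break
            f_par = _draw_retention(
                rng, config.parenchyma_retention_mean, config.retention_sd
            )
        kinetics = replace(
            base,
            a0_nodule=base.a0_nodule * config.count_scale,
            a0_parenchyma=base.a0_parenchyma * config.count_scale,
            a0_body_background=base.a0_body_background * config.count_scale,
            f_nodule=f_nodule,
            f_parenchyma=f_par,
            f_background=config.background_retention,
            apply_physical_decay=config.apply_physical_decay,
        )
        patient_seed = (
            int(rng.integers(2**31)) if config.noise == "poisson" else None
        )
        phantom = build_phantom(
            geometry=config.geometry,
            kinetics=kinetics,
            times=config.times,
            frame_s=config.frame_s,
            noise=config.noise,
            seed=patient_seed,
        )
        patients.append(
            SimulatedPatient(
                patient_id=idx,
                phantom=phantom,
                malignant=bool(malignant),
                kinetics=kinetics,
            )
        )
    return patients
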