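"""ROI count statistics, geometric mirroring, and physical decay correction.

All quantification downstream works on *mean counts per pixel* within an
ROI, so unequal ROI areas never bias an index; area correction for
background activity is automatic under per-pixel means.

Decay correction rescales counts measured ``t`` minutes post-injection to a
common reference time by ``2**((t - t_ref) / T_half)``.  For Tc-99m the
half-life is 360.4 min (6.007 h).  Correction is OFF by default: with both
frames of a study corrected to the same reference it cancels exactly in the
retention index and shifts the wash-out index by a single analytic factor,
so the uncorrected numbers are the primary ones and the corrected variant is
exposed for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .study_io import PlanarImage, RoiLabel, RoiMask

__all__ = [
    "TC99M_HALF_LIFE_MIN",
    "RoiStats",
    "DecaySpec",
    "roi_mean_counts",
    "mirror_roi",
    "copy_roi_to_late",
    "decay_correct",
]

#: Physical half-life of Tc-99m in minutes (6.007 h).
TC99M_HALF_LIFE_MIN = 360.4


@dataclass(frozen=True)
class RoiStats:
    """Count statistics of one ROI on one frame.

    Before decay correction ``mean_counts_per_pixel * n_pixels ==
    total_counts`` exactly; after correction both are scaled by the same
    real factor, so the identity still holds (in floating point).
    """

    mean_counts_per_pixel: float
    n_pixels: int
    total_counts: float
    t_acq_min: float
    label: RoiLabel
    decay_corrected: bool = False

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")
        if self.mean_counts_per_pixel < 0 or self.total_counts < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class DecaySpec:
    """How (and whether) to correct counts for physical isotope decay."""

    half_life_min: float = TC99M_HALF_LIFE_MIN
    reference_time_min: float = 0.0
    enabled: bool = False

    def __post_init__(self) -> None:
        if self.half_life_min <= 0:
            raise ValueError("half_life_min must be positive")

    def factor(self, t_acq_min: float) -> float:
        """Multiplier taking counts at ``t_acq_min`` back to the reference time."""
        return 2.0 ** ((t_acq_min - self.reference_time_min) / self.half_life_min)


def roi_mean_counts(image: PlanarImage, roi: RoiMask) -> RoiStats:
    """Mean and total counts of ``roi`` on ``image``.

    The ROI grid must match the image grid; the result carries the frame's
    acquisition time so the indices can be computed time-aware.
    """
    if roi.source_grid != image.matrix_size:
        raise ValueError(
            f"ROI grid {roi.source_grid} does not match image grid {image.matrix_size}"
        )
    rows, cols = roi.to_indices()
    values = image.counts[rows, cols]
    total = float(values.sum())
    n = roi.n_pixels
    return RoiStats(
        mean_counts_per_pixel=total / n,
        n_pixels=n,
        total_counts=total,
        t_acq_min=image.t_acq_min,
        label=roi.label,
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def mirror_roi(roi: RoiMask, axis_col: float, new_label: RoiLabel) -> RoiMask:
    """Reflect an ROI about the vertical line ``col == axis_col``.

    Reflected columns are ``round(2 * axis_col - c)`` with half-away-from-zero
    rounding, so for integer or half-integer axes the operation is an exact
    involution.  A reflection overlapping the source ROI (a mis-placed
    background, e.g. an axis inside the nodule) is flagged on the result
    rather than rejected.
    """
    rows, cols = roi.source_grid
    mirrored = set()
    for r, c in roi.pixels:
        c2 = _round_half_away(2.0 * axis_col - c)
        if not (0 <= c2 < cols):
            raise ValueError(
                f"mirrored pixel ({r}, {c2}) falls outside the grid "
                f"(axis_col={axis_col})"
            )
        mirrored.add((r, c2))
    warnings = ()
    if mirrored & roi.pixels:
        warnings = ("mirror_overlaps_source",)
    return RoiMask(
        pixels=frozenset(mirrored),
        label=new_label,
        source_grid=roi.source_grid,
        warnings=warnings,
    )


def copy_roi_to_late(
    roi: RoiMask,
    early_grid: tuple[int, int],
    late_grid: tuple[int, int],
    scale: float | None = None,
) -> RoiMask:
    """Copy an early-image ROI onto the late image grid.

    Identical grids copy verbatim.  Differing grids require an explicitly
    declared ``scale`` (late/early matrix ratio); pixels are remapped through
    their centres, ``new = floor((coord + 0.5) * scale)``, and duplicates
    collapse.
    """
    if tuple(roi.source_grid) != tuple(early_grid):
        raise ValueError(
            f"ROI grid {roi.source_grid} does not match declared early grid {early_grid}"
        )
    if tuple(early_grid) == tuple(late_grid):
        if scale is not None and scale != 1:
            raise ValueError("scale declared but grids are identical")
        return replace(roi, source_grid=tuple(late_grid))
    if scale is None:
        raise ValueError(
            f"grids differ ({early_grid} -> {late_grid}) and no scale was declared"
        )
    expected = (late_grid[0] / early_grid[0], late_grid[1] / early_grid[1])
    if not np.allclose(expected, (scale, scale)):
        raise ValueError(
            f"declared scale {scale} inconsistent with grid ratio {expected}"
        )
    remapped = set()
    for r, c in roi.pixels:
        r2 = int(math.floor((r + 0.5) * scale))
        c2 = int(math.floor((c + 0.5) * scale))
        if not (0 <= r2 < late_grid[0] and 0 <= c2 < late_grid[1]):
            raise ValueError(f"remapped pixel ({r2}, {c2}) outside late grid")
        remapped.add((r2, c2))
    return RoiMask(pixels=frozenset(remapped), label=roi.label, source_grid=tuple(late_grid))


def decay_correct(stats: RoiStats, spec: DecaySpec) -> RoiStats:
    """Rescale ROI statistics to the decay reference time.

    Mean and total are multiplied by the same ``2**((t - t_ref)/T_half)``
    factor; the pixel count is untouched.
    """
    if not spec.enabled:
        raise ValueError("decay correction requested with spec.enabled == False")
    k = spec.factor(stats.t_acq_min)
    return replace(
        stats,
        mean_counts_per_pixel=stats.mean_counts_per_pixel * k,
        total_counts=stats.total_counts * k,
        decay_corrected=True,
    )
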