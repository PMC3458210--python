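"""H/M ratio and washout-rate quantification.

Symbols follow the standard planar MIBG convention: ``H`` is the mean counts
per pixel in the cardiac ROI and ``M`` the mean counts per pixel in the
mediastinal ROI, on the early (``e``) and delayed/late (``l``) images.

* H/M ratio: ``H / M`` (no background correction).
* Washout rate, method 1 (no background correction)::

      WR = (H_e - H_l) / H_e * 100

* Washout rate, method 2 (mediastinal-background corrected)::

      WR_bkg = [(H_e - M_e) - (H_l - M_l)] / (H_e - M_e) * 100

Physical 123-I time decay is *not* corrected for by default; an optional
decay correction (half-life 13.2 h) is available for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

from .image import PlanarImage
from .roi import ROISet, ROIStats, roi_stats

#: physical half-life of 123-I, hours
IODINE123_HALF_LIFE_H = 13.2


class DegenerateUptakeError(ValueError):
    """Raised when counts make a ratio or washout formula undefined."""


@dataclass(frozen=True)
class UptakeMeasures:
    """All per-study quantities derived from one early/delayed image pair."""

    H_e: float
    M_e: float
    H_l: float
    M_l: float
    hm_early: float
    hm_delayed: float
    wr_m1_pct: float
    wr_m2_pct: float
    cardiac_roi_kind: str = "polygon"
    cardiac_pixels_early: int | None = None
    cardiac_pixels_delayed: int | None = None


def hm_ratio(cardiac: ROIStats | float, mediastinal: ROIStats | float) -> float:
    """Heart-to-mediastinum ratio: mean cardiac counts / mean mediastinal counts."""
    h = cardiac.mean_counts if isinstance(cardiac, ROIStats) else float(cardiac)
    m = mediastinal.mean_counts if isinstance(mediastinal, ROIStats) else float(mediastinal)
    if m <= 0:
        raise DegenerateUptakeError("mediastinal mean counts must be positive")
    return h / m


def washout_m1(H_e: float, H_l: float) -> float:
    """Washout rate without background correction, percent."""
    if H_e <= 0:
        raise DegenerateUptakeError("early cardiac mean counts must be positive")
    return (H_e - H_l) / H_e * 100.0


def washout_m2(H_e: float, M_e: float, H_l: float, M_l: float) -> float:
    """Washout rate with mediastinal background correction, percent.

    Raises :class:`DegenerateUptakeError` when the background-corrected early
    uptake ``H_e - M_e`` is non-positive (possible with severe cardiac
    denervation); the caller decides how to handle such studies.
    """
    if H_e - M_e <= 0:
        raise DegenerateUptakeError("non-positive background-corrected early uptake")
    return ((H_e - M_e) - (H_l - M_l)) / (H_e - M_e) * 100.0


def decay_correction_factor(early: PlanarImage, delayed: PlanarImage) -> float:
    """Factor that scales delayed counts up to the early acquisition time.

    Uses the 13.2 h physical half-life of 123-I and the images' acquisition
    offsets.  Only relevant when decay correction is explicitly requested.
    """
    dt_h = (delayed.acquisition_offset_min - early.acquisition_offset_min) / 60.0
    if dt_h < 0:
        raise ValueError("delayed image acquired before early image")
    return 2.0 ** (dt_h / IODINE123_HALF_LIFE_H)


def quantify_study(
    early: PlanarImage,
    delayed: PlanarImage,
    roi_set: ROISet,
    cardiac: str = "polygon",
    roi_set_delayed: ROISet | None = None,
    decay_correct: bool = False,
    on_degenerate_wr2: str = "raise",
) -> UptakeMeasures:
    """Quantify one early/delayed pair with a given set of ROIs.

    ``roi_set`` is applied to the early image.  By default the same ROI
    definitions are applied to the delayed image; pass ``roi_set_delayed`` for
    observers who redrew their ROIs independently on each phase.  ``cardiac``
    selects the cardiac ROI geometry: ``"polygon"`` (manual), ``"oval"`` or
    ``"circle"`` (fixed-size).

    ``on_degenerate_wr2`` controls what happens when the background-corrected
    early uptake is non-positive and method-2 washout is undefined:
    ``"raise"`` (default) propagates the error, ``"nan"`` records NaN so
    cohort pipelines can treat the study as missing for that measurand.
    """
    if on_degenerate_wr2 not in ("raise", "nan"):
        raise ValueError("on_degenerate_wr2 must be 'raise' or 'nan'")
    if early.phase != "early" or delayed.phase != "delayed":
        raise ValueError("quantify_study expects (early, delayed) images in that order")
    rois_l = roi_set_delayed if roi_set_delayed is not None else roi_set

    card_e = roi_stats(early, roi_set.cardiac(cardiac))
    med_e = roi_stats(early, roi_set.mediastinal_rect)
    card_l = roi_stats(delayed, rois_l.cardiac(cardiac))
    med_l = roi_stats(delayed, rois_l.mediastinal_rect)

    H_e, M_e = card_e.mean_counts, med_e.mean_counts
    H_l, M_l = card_l.mean_counts, med_l.mean_counts
    if decay_correct:
        f = decay_correction_factor(early, delayed)
        H_l *= f
        M_l *= f

    try:
        wr2 = washout_m2(H_e, M_e, H_l, M_l)
    except DegenerateUptakeError:
        if on_degenerate_wr2 == "raise":
            raise
        wr2 = float("nan")

    return UptakeMeasures(
        H_e=H_e,
        M_e=M_e,
        H_l=H_l,
        M_l=M_l,
        hm_early=hm_ratio(H_e, M_e),
        hm_delayed=hm_ratio(H_l, M_l),
        wr_m1_pct=washout_m1(H_e, H_l),
        wr_m2_pct=wr2,
        cardiac_roi_kind=cardiac,
        cardiac_pixels_early=card_e.pixel_count,
        cardiac_pixels_delayed=card_l.pixel_count,
    )
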