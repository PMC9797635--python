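"""Template methods on composite images: TwoBox (SBR) and ThreeBox (TBPI).

TwoBox places two large standardized trapezoidal ROIs (44.8 x 38.4 mm
bounding box) over the right and left striatum of the all-slices composite so
that essentially all striatal counts - including partial-volume spill-out -
are recorded, derives a reference region semi-automatically
(mask out the templates, smooth, 50 % threshold), and converts total template
counts to a Specific Binding Ratio with the known striatal volume as the
weighting factor:

    SBR = (1 / V_ST) * (Ct_ROI(s) / c_ns - V_ROI(s))

ThreeBox instead uses per-side rectangles over the striatum with an
equal-area reference rectangle immediately posterior, and reports the Total
Binding Potential Index:

    TBPI = (1 / V_ST) * (Ct_ROI(s) - c_ns * V_ns) / (c_ns * V_ns)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .composite import Composite2D, composite_all_striatal
from .phantom import Acquisition, PhantomGeometry
from .results import QuantResult

__all__ = [
    "TemplateRoi",
    "ReferenceRegion",
    "DEFAULT_BOX_MM",
    "place_striatal_templates",
    "twobox_reference",
    "twobox_sbr",
    "threebox_rois",
    "threebox_tbpi",
    "quantify_twobox",
    "quantify_threebox",
]

#: template bounding box, mm: (left-right extent, anterior-posterior extent)
DEFAULT_BOX_MM = (38.4, 44.8)

#: ratio of the trapezoid's medial (short) to lateral (long) parallel side
TRAPEZOID_TOP_RATIO = 0.7


@dataclass
class TemplateRoi:
    """A standardized geometric ROI placed on a composite image."""

    shape: str                      # 'trapezoid' or 'rectangle'
    dimensions_mm: tuple[float, float]
    center_mm: tuple[float, float]
    mask: np.ndarray
    area_mm2: float
    volume_ml: float                # area x composite effective thickness


@dataclass
class ReferenceRegion:
    """Non-specific reference region of a composite image."""

    mask: np.ndarray
    mean_counts: float              # counts per pixel, from the unsmoothed image
    concentration: float            # counts per mL of composite slab


def _mm_grids(composite: Composite2D):
    nx, ny = composite.image.shape
    xs = (np.arange(nx) - (nx - 1) / 2.0) * composite.pixel_size
    ys = (np.arange(ny) - (ny - 1) / 2.0) * composite.pixel_size
    return np.meshgrid(xs, ys, indexing="ij")


def _side_centroids(
    composite: Composite2D, striatal_proj: np.ndarray | None = None
) -> dict[str, tuple[float, float]]:
    """Striatal count centroids of the right (x<0) and left (x>0) sides,
    symmetrized about the midline (within one pixel).

    The centroid is count-weighted over the striatal footprint: the projected
    ground-truth striatal mask when available (simulation studies), otherwise
    the top-decile pixels of the composite (mask-free fallback)."""
    xg, yg = _mm_grids(composite)
    img = composite.image
    if striatal_proj is None:
        striatal_proj = img >= np.percentile(img, 90)
    cents = {}
    for side, sel in (("R", xg < 0), ("L", xg >= 0)):
        w = img * (sel & striatal_proj)
        tot = w.sum()
        if tot <= 0:
            raise ValueError(f"no striatal counts on side {side}")
        cents[side] = ((xg * w).sum() / tot, (yg * w).sum() / tot)
    x_off = (abs(cents["R"][0]) + abs(cents["L"][0])) / 2.0
    y_c = (cents["R"][1] + cents["L"][1]) / 2.0
    return {"R": (-x_off, y_c), "L": (x_off, y_c)}


def _check_bounds(composite: Composite2D, center, box_mm) -> None:
    xg, yg = _mm_grids(composite)
    hx, hy = box_mm[0] / 2.0, box_mm[1] / 2.0
    if (
        center[0] - hx < xg.min() or center[0] + hx > xg.max()
        or center[1] - hy < yg.min() or center[1] + hy > yg.max()
    ):
        raise ValueError(f"template centered at {center} mm leaves the image")


def _trapezoid_mask(composite: Composite2D, center, box_mm, top_ratio) -> np.ndarray:
    """Isosceles trapezoid: parallel sides run anterior-posterior, the wider
    one lateral (away from the midline)."""
    xg, yg = _mm_grids(composite)
    wx, hy = box_mm
    lateral = 1.0 if center[0] >= 0 else -1.0
    u = ((xg - center[0]) * lateral + wx / 2.0) / wx  # 0 medial edge -> 1 lateral
    inside_x = (u >= 0) & (u <= 1)
    half_h = hy / 2.0 * (top_ratio + (1.0 - top_ratio) * u)
    return inside_x & (np.abs(yg - center[1]) <= half_h)


def _rect_mask(composite: Composite2D, center, box_mm) -> np.ndarray:
    xg, yg = _mm_grids(composite)
    return (np.abs(xg - center[0]) <= box_mm[0] / 2.0) & (
        np.abs(yg - center[1]) <= box_mm[1] / 2.0
    )


def _make_roi(composite, shape, center, box_mm, mask) -> TemplateRoi:
    area = float(mask.sum()) * composite.pixel_size ** 2
    return TemplateRoi(
        shape=shape,
        dimensions_mm=tuple(box_mm),
        center_mm=tuple(center),
        mask=mask,
        area_mm2=area,
        volume_ml=area * composite.thickness_mm / 1000.0,
    )


def place_striatal_templates(
    composite: Composite2D,
    centers: dict[str, tuple[float, float]] | None = None,
    box_mm: tuple[float, float] = DEFAULT_BOX_MM,
    top_ratio: float = TRAPEZOID_TOP_RATIO,
    striatal_proj: np.ndarray | None = None,
) -> dict[str, TemplateRoi]:
    """Place the two TwoBox trapezoids over the right/left striatum.

    Defaults to the per-side striatal count centroids, symmetrized about the
    midline.  Raises if a template leaves the image or the two overlap.
    """
    if centers is None:
        centers = _side_centroids(composite, striatal_proj)
    rois = {}
    for side in ("R", "L"):
        _check_bounds(composite, centers[side], box_mm)
        mask = _trapezoid_mask(composite, centers[side], box_mm, top_ratio)
        rois[side] = _make_roi(composite, "trapezoid", centers[side], box_mm, mask)
    if np.any(rois["R"].mask & rois["L"].mask):
        raise ValueError("striatal templates overlap each other")
    return rois


def twobox_reference(
    composite: Composite2D,
    striatal_rois: dict[str, TemplateRoi],
    n_passes: int = 3,
    threshold: float = 0.5,
) -> ReferenceRegion:
    """Semi-automated TwoBox reference region.

    (1) zero out both striatal templates (intrinsic binary mask); (2) smooth
    the remainder with a 3x3 mean filter applied ``n_passes`` times; (3) keep
    pixels at or above ``threshold`` of the smoothed remainder's maximum.  The
    mean reference level c_ns is measured on the *unsmoothed* composite over
    that mask - smoothing only defines the geometry.
    """
    template_union = striatal_rois["R"].mask | striatal_rois["L"].mask
    work = composite.image.astype(np.float64).copy()
    work[template_union] = 0.0
    for _ in range(n_passes):
        work = ndimage.uniform_filter(work, size=3, mode="constant")
    mask = (work >= threshold * work.max()) & ~template_union
    if not mask.any():
        raise ValueError("empty TwoBox reference region")
    mean_counts = float(composite.image[mask].mean())
    return ReferenceRegion(
        mask=mask,
        mean_counts=mean_counts,
        concentration=mean_counts / composite.pixel_volume_ml,
    )


def twobox_sbr(total_counts_roi: float, c_ns: float, v_st: float, v_roi: float) -> float:
    """Specific Binding Ratio of one striatal template.

    SBR = (1/V_ST) * (Ct_ROI(s)/c_ns - V_ROI(s)), with c_ns the reference
    concentration (counts/mL), V_ST the known striatal volume and V_ROI the
    geometric volume of the template (area x composite thickness).
    """
    if c_ns <= 0:
        raise ValueError("reference concentration must be positive")
    if v_st <= 0:
        raise ValueError("striatal volume must be positive")
    if v_roi < v_st:
        raise ValueError("template volume is smaller than the target volume")
    return (total_counts_roi / c_ns - v_roi) / v_st


def threebox_rois(
    composite: Composite2D,
    centers: dict[str, tuple[float, float]] | None = None,
    box_mm: tuple[float, float] = DEFAULT_BOX_MM,
    striatal_proj: np.ndarray | None = None,
) -> dict[str, tuple[TemplateRoi, TemplateRoi]]:
    """Per-side ThreeBox rectangles: a striatal box on the count maximum and
    an equal-area reference box immediately posterior (adjacent, disjoint)."""
    if centers is None:
        centers = _side_centroids(composite, striatal_proj)
    out = {}
    for side in ("R", "L"):
        st_center = centers[side]
        ref_center = (st_center[0], st_center[1] - box_mm[1])
        _check_bounds(composite, st_center, box_mm)
        _check_bounds(composite, ref_center, box_mm)  # raises if it leaves the image
        st_mask = _rect_mask(composite, st_center, box_mm)
        ref_mask = _rect_mask(composite, ref_center, box_mm) & ~st_mask
        out[side] = (
            _make_roi(composite, "rectangle", st_center, box_mm, st_mask),
            _make_roi(composite, "rectangle", ref_center, box_mm, ref_mask),
        )
    return out


def threebox_tbpi(total_counts_roi: float, c_ns: float, v_ns: float, v_st: float) -> float:
    """Total Binding Potential Index of one striatal box.

    TBPI = (1/V_ST) * (Ct_ROI(s) - c_ns*V_ns) / (c_ns*V_ns); callers report it
    x100 as a percentage.
    """
    if v_st <= 0:
        raise ValueError("striatal volume must be positive")
    denom = c_ns * v_ns
    if denom <= 0:
        raise ValueError("reference term c_ns*V_ns must be positive")
    return (total_counts_roi - denom) / denom / v_st


def _pooled(values: dict[str, float], weights: dict[str, float]) -> float:
    tot = sum(weights.values())
    return sum(values[s] * weights[s] for s in values) / tot


def quantify_twobox(
    acq: Acquisition,
    geometry: PhantomGeometry,
    threshold_fraction: float = 0.05,
) -> list[QuantResult]:
    """TwoBox striatal SBR of one acquisition (volume-weighted over sides)."""
    mask3d = geometry.striatal_mask
    comp = composite_all_striatal(acq, mask3d, threshold_fraction)
    proj = mask3d[:, :, comp.slice_indices].any(axis=2)
    templates = place_striatal_templates(comp, striatal_proj=proj)
    ref = twobox_reference(comp, templates)
    sbr, vols = {}, {}
    for side in ("R", "L"):
        t = templates[side]
        ct = float(comp.image[t.mask].sum())
        vols[side] = geometry.side_volume_ml(side)
        sbr[side] = twobox_sbr(ct, ref.concentration, vols[side], t.volume_ml)
    return [
        QuantResult(
            method="twobox",
            compartment="ST",
            index_type="SBR",
            value=_pooled(sbr, vols),
            acquisition_id=acq.acquisition_id,
        )
    ]


def quantify_threebox(
    acq: Acquisition,
    geometry: PhantomGeometry,
    threshold_fraction: float = 0.05,
) -> list[QuantResult]:
    """ThreeBox striatal TBPI of one acquisition, reported in percent."""
    mask3d = geometry.striatal_mask
    comp = composite_all_striatal(acq, mask3d, threshold_fraction)
    proj = mask3d[:, :, comp.slice_indices].any(axis=2)
    rois = threebox_rois(comp, striatal_proj=proj)
    tbpi, vols = {}, {}
    for side in ("R", "L"):
        st_roi, ref_roi = rois[side]
        ct = float(comp.image[st_roi.mask].sum())
        c_ns = float(comp.image[ref_roi.mask].mean()) / comp.pixel_volume_ml
        vols[side] = geometry.side_volume_ml(side)
        tbpi[side] = threebox_tbpi(ct, c_ns, ref_roi.volume_ml, vols[side])
    return [
        QuantResult(
            method="threebox",
            compartment="ST",
            index_type="TBPI",
            value=100.0 * _pooled(tbpi, vols),
            acquisition_id=acq.acquisition_id,
        )
    ]
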