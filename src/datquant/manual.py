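"""Manual ROI method: anatomical ROIs on the top-5-slice composite and BPI.

The human step of tracing each striatal compartment on the composite image is
emulated deterministically: each specific ROI is the 2-D projection of the
compartment's true label across the selected slices, i.e. an operator who
traces the visible anatomical boundary perfectly.  Such ROIs capture the
in-boundary counts but none of the counts blurred out of the boundary by the
system resolution, which is precisely the partial-volume mechanism that makes
the manual method underestimate binding.

BPI = (C_ROI(s) - C_ROI(ns)) / C_ROI(ns), with C the average counts per pixel
in the specific and in the non-specific (reference) ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .composite import Composite2D, composite_top_k
from .phantom import Acquisition, PhantomGeometry, LABELS, COMPARTMENTS
from .results import QuantResult

__all__ = [
    "RoiMask2D",
    "derive_manual_rois",
    "reference_roi_lowcount",
    "compute_bpi",
    "quantify_manual",
]


@dataclass
class RoiMask2D:
    """A 2-D region of interest on a composite image."""

    mask: np.ndarray
    area_mm2: float
    label: str

    @classmethod
    def from_mask(cls, mask: np.ndarray, pixel_size: float, label: str) -> "RoiMask2D":
        return cls(mask=mask, area_mm2=float(mask.sum()) * pixel_size ** 2, label=label)


def derive_manual_rois(
    geometry: PhantomGeometry, composite: Composite2D
) -> dict[str, RoiMask2D]:
    """Anatomical-projection ROIs for CA/PU (both sides) plus the ST unions.

    Each compartment ROI is the logical-OR projection of its label over the
    composite's slices; ST_R / ST_L are the unions of the side's caudate and
    putamen ROIs (disjoint by construction).
    """
    if geometry.shape[:2] != composite.image.shape:
        raise ValueError("composite does not match the phantom geometry")
    idx = np.asarray(composite.slice_indices, dtype=int)
    rois: dict[str, RoiMask2D] = {}
    for name in COMPARTMENTS:
        proj = (geometry.label_volume[:, :, idx] == LABELS[name]).any(axis=2)
        if not proj.any():
            raise ValueError(
                f"compartment {name} does not intersect the selected slices"
            )
        rois[name] = RoiMask2D.from_mask(proj, composite.pixel_size, name)
    for side in ("R", "L"):
        union = rois[f"CA_{side}"].mask | rois[f"PU_{side}"].mask
        rois[f"ST_{side}"] = RoiMask2D.from_mask(union, composite.pixel_size, f"ST_{side}")
    return rois


def reference_roi_lowcount(
    composite: Composite2D,
    geometry: PhantomGeometry,
    margin_mm: float = 20.0,
    min_pixels: int = 50,
) -> RoiMask2D:
    """Reference ROI in a low-count part of the composite.

    Pixels of the brain-shell projection at least ``margin_mm`` (in-plane
    Euclidean) from every striatal ROI pixel, restricted to the posterior
    third of the shell projection - the synthetic analogue of an occipital
    reference placement, safely clear of striatal spill-over.
    """
    idx = np.asarray(composite.slice_indices, dtype=int)
    labels = geometry.label_volume[:, :, idx]
    # intersection across slices: reference columns must be background in
    # every summed slice, otherwise edge pixels dilute the reference level
    shell_proj = (labels == LABELS["shell"]).all(axis=2)
    striatal_proj = (labels >= LABELS["CA_R"]).any(axis=2)
    if not striatal_proj.any():
        raise ValueError("no striatal pixels in the selected slices")
    dist_mm = ndimage.distance_transform_edt(~striatal_proj) * composite.pixel_size

    ys = np.where(shell_proj.any(axis=0))[0]
    y_cut = ys.min() + (ys.max() - ys.min()) / 3.0  # posterior = low y
    posterior = np.zeros_like(shell_proj)
    posterior[:, : int(np.floor(y_cut)) + 1] = True

    mask = shell_proj & posterior & (dist_mm >= margin_mm)
    if mask.sum() < min_pixels:
        raise ValueError(
            f"only {int(mask.sum())} reference pixels qualify (< {min_pixels})"
        )
    return RoiMask2D.from_mask(mask, composite.pixel_size, "reference")


def compute_bpi(mean_specific: float, mean_nonspecific: float) -> float:
    """Binding Potential Index from mean counts per pixel.

    BPI = (C_ROI(s) - C_ROI(ns)) / C_ROI(ns).
    """
    if mean_nonspecific <= 0:
        raise ValueError("non-specific mean counts must be positive")
    return (mean_specific - mean_nonspecific) / mean_nonspecific


def quantify_manual(
    acq: Acquisition, geometry: PhantomGeometry, k: int = 5
) -> list[QuantResult]:
    """Manual-method BPI for CA, PU and ST (counts pooled across sides)."""
    comp = composite_top_k(acq, geometry.striatal_mask, k=k)
    rois = derive_manual_rois(geometry, comp)
    ref = reference_roi_lowcount(comp, geometry)
    c_ns = float(comp.image[ref.mask].mean())
    out = []
    for comp_name, parts in (
        ("CA", ("CA_R", "CA_L")),
        ("PU", ("PU_R", "PU_L")),
        ("ST", ("ST_R", "ST_L")),
    ):
        pooled = np.zeros_like(rois[parts[0]].mask)
        for p in parts:
            pooled |= rois[p].mask
        c_s = float(comp.image[pooled].mean())
        out.append(
            QuantResult(
                method="manual",
                compartment=comp_name,
                index_type="BPI",
                value=compute_bpi(c_s, c_ns),
                acquisition_id=acq.acquisition_id,
            )
        )
    return out
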