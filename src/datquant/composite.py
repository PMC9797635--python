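"""Composite 2-D images (CI-2D) from a 3-D acquisition.

Both the manual and the template methods work on a single 2-D image obtained
by summing transaxial slices that carry striatal counts: the manual method
uses the five slices with the highest striatal count density, the template
methods use every slice with appreciable striatal counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import Acquisition

__all__ = ["Composite2D", "composite_top_k", "composite_all_striatal", "save_composite"]


@dataclass
class Composite2D:
    """Summed transaxial count image with its slice bookkeeping."""

    image: np.ndarray
    slice_indices: list[int]
    pixel_size: float
    slice_thickness: float

    @property
    def n_slices(self) -> int:
        return len(self.slice_indices)

    @property
    def thickness_mm(self) -> float:
        """Effective thickness of the quantified slab."""
        return self.n_slices * self.slice_thickness

    @property
    def pixel_volume_ml(self) -> float:
        """Volume represented by one composite pixel (full slab depth)."""
        return self.pixel_size ** 2 * self.thickness_mm / 1000.0


def _striatal_slice_counts(acq: Acquisition, striatal_mask: np.ndarray) -> np.ndarray:
    if striatal_mask.shape != acq.counts_volume.shape:
        raise ValueError("striatal_mask shape does not match the acquisition")
    if not striatal_mask.any():
        raise ValueError("striatal_mask is empty")
    return (acq.counts_volume * striatal_mask).sum(axis=(0, 1))


def _build(acq: Acquisition, idx: np.ndarray) -> Composite2D:
    idx = np.sort(np.asarray(idx, dtype=int))
    image = acq.counts_volume[:, :, idx].sum(axis=2)
    return Composite2D(
        image=image,
        slice_indices=[int(i) for i in idx],
        pixel_size=acq.config.voxel_size,
        slice_thickness=acq.config.voxel_size,
    )


def composite_top_k(acq: Acquisition, striatal_mask: np.ndarray, k: int = 5) -> Composite2D:
    """Sum the ``k`` transaxial slices with the highest striatal counts.

    Ties are broken in favor of the lower slice index.  Default ``k=5``
    matches the manual workflow of picking the five densest striatal slices.
    """
    per_slice = _striatal_slice_counts(acq, striatal_mask)
    if not 1 <= k <= per_slice.size:
        raise ValueError(f"k must be in [1, {per_slice.size}]")
    order = np.argsort(-per_slice, kind="stable")  # stable => lower index wins ties
    return _build(acq, order[:k])


def composite_all_striatal(
    acq: Acquisition, striatal_mask: np.ndarray, threshold_fraction: float = 0.05
) -> Composite2D:
    """Sum every slice whose striatal counts exceed a fraction of the peak.

    A slice is included when its counts inside ``striatal_mask`` exceed
    ``threshold_fraction`` (default 5 %) of the maximum per-slice striatal
    counts; this keeps the slices traversing the striatal wells and rejects
    noise-only slices.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    per_slice = _striatal_slice_counts(acq, striatal_mask)
    sel = np.where(per_slice > threshold_fraction * per_slice.max())[0]
    if sel.size == 0:
        raise ValueError("no slice passes the striatal count threshold")
    return _build(acq, sel)


def save_composite(comp: Composite2D, path) -> Path:
    """Write a composite as a single-slice NIfTI plus a JSON sidecar."""
    path = Path(path)
    aff = np.diag([comp.pixel_size, comp.pixel_size, comp.thickness_mm, 1.0])
    img = nib.Nifti1Image(comp.image[:, :, None].astype(np.float32), aff)
    nib.save(img, path)
    sidecar = {
        "slice_indices": comp.slice_indices,
        "pixel_size": comp.pixel_size,
        "slice_thickness": comp.slice_thickness,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path
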