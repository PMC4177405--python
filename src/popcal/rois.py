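"""Soma and neuropil regions of interest and trace extraction.

ROIs are circular or annular (nucleus-excluded) regions defined in µm;
pixel membership uses the half-open convention: a pixel belongs to a
region when its center, at ``(index + 0.5) * pixel_size``, satisfies
``inner_radius <= distance < outer_radius``.  A cell's trace is the
arithmetic mean of its masked pixels per frame.  The neuropil trace is
the mean over a 20 µm disk around the cell center excluding every soma
mask in the set (not only the cell's own).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateNeuropilError, InvalidRoiError

__all__ = ["Roi", "RoiSet", "extract_trace", "neuropil_trace", "choose_roi_kind"]


def _disk_mask(
    center_um: tuple[float, float],
    outer_um: float,
    inner_um: float,
    pixel_size: float,
    image_size: tuple[int, int],
) -> np.ndarray:
    h, w = image_size
    yy, xx = np.meshgrid(
        (np.arange(h) + 0.5) * pixel_size,
        (np.arange(w) + 0.5) * pixel_size,
        indexing="ij",
    )
    d2 = (yy - center_um[0]) ** 2 + (xx - center_um[1]) ** 2
    return (d2 < outer_um**2) & (d2 >= inner_um**2)


@dataclass
class Roi:
    """One soma ROI: circular disk or annular ring, in physical units."""

    center: tuple[float, float]  # (row, col) in µm
    kind: str  # "circular" | "annular"
    outer_radius: float  # µm
    inner_radius: float = 0.0  # µm; 0 for circular
    pixel_mask: np.ndarray | None = None  # boolean (H, W), built lazily

    def __post_init__(self) -> None:
        if self.kind not in ("circular", "annular"):
            raise InvalidRoiError(f"unknown ROI kind {self.kind!r}")
        if not self.inner_radius < self.outer_radius:
            raise InvalidRoiError("inner_radius must be < outer_radius")
        if self.kind == "circular" and self.inner_radius != 0.0:
            raise InvalidRoiError("circular ROI must have inner_radius 0")

    def build_mask(self, pixel_size: float, image_size: tuple[int, int]) -> np.ndarray:
        """Materialize (and cache) the boolean pixel mask."""
        mask = _disk_mask(
            self.center, self.outer_radius, self.inner_radius, pixel_size, image_size
        )
        if not mask.any():
            raise InvalidRoiError(
                f"ROI at {self.center} µm has an empty mask at "
                f"pixel size {pixel_size} µm"
            )
        self.pixel_mask = mask
        return mask


@dataclass
class RoiSet:
    """A set of soma ROIs sharing one image geometry."""

    rois: list[Roi]
    pixel_size: float  # µm/pixel
    image_size: tuple[int, int]  # (rows, cols)

    def __post_init__(self) -> None:
        h, w = self.image_size
        for roi in self.rois:
            cy, cx = roi.center
            if not (0 <= cy <= h * self.pixel_size and 0 <= cx <= w * self.pixel_size):
                raise InvalidRoiError(f"ROI center {roi.center} outside image bounds")
            roi.build_mask(self.pixel_size, self.image_size)

    def __len__(self) -> int:
        return len(self.rois)

    def soma_union(self) -> np.ndarray:
        """Union of all soma disks (annular interiors included)."""
        union = np.zeros(self.image_size, dtype=bool)
        for roi in self.rois:
            union |= _disk_mask(
                roi.center, roi.outer_radius, 0.0, self.pixel_size, self.image_size
            )
        return union

    # ------------------------------------------------------------------
    # tabular round trip (id, kind, row, col, inner_r, outer_r in µm)
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(len(self.rois)),
                "kind": [r.kind for r in self.rois],
                "row_um": [r.center[0] for r in self.rois],
                "col_um": [r.center[1] for r in self.rois],
                "inner_r_um": [r.inner_radius for r in self.rois],
                "outer_r_um": [r.outer_radius for r in self.rois],
            }
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, pixel_size: float, image_size: tuple[int, int]
    ) -> "RoiSet":
        rois = [
            Roi(
                center=(row.row_um, row.col_um),
                kind=row.kind,
                outer_radius=row.outer_r_um,
                inner_radius=row.inner_r_um,
            )
            for row in df.itertuples()
        ]
        return cls(rois=rois, pixel_size=pixel_size, image_size=image_size)


def extract_trace(stack: np.ndarray, roi: Roi) -> np.ndarray:
    """Mean fluorescence of the ROI's pixels, one value per frame."""
    if roi.pixel_mask is None:
        raise InvalidRoiError("ROI mask not built; add the ROI to a RoiSet first")
    mask = roi.pixel_mask
    if not mask.any():
        raise InvalidRoiError("ROI mask is empty")
    if stack.shape[-2:] != mask.shape:
        raise InvalidRoiError(
            f"stack frames {stack.shape[-2:]} do not match mask {mask.shape}"
        )
    return stack[..., mask].mean(axis=-1)


def neuropil_trace(
    stack: np.ndarray,
    roi_set: RoiSet,
    cell_index: int,
    radius: float = 20.0,
) -> np.ndarray:
    """Neuropil trace for one cell: mean over a ``radius`` µm disk around
    the cell center, excluding every soma disk in ``roi_set``.

    The exclusion removes whole soma disks, including the nuclear
    interior of annular ROIs and the cell's own soma.
    """
    roi = roi_set.rois[cell_index]
    region = _disk_mask(roi.center, radius, 0.0, roi_set.pixel_size, roi_set.image_size)
    region &= ~roi_set.soma_union()
    if not region.any():
        raise DegenerateNeuropilError(
            f"neuropil region of cell {cell_index} is fully covered by somata"
        )
    return stack[..., region].mean(axis=-1)


def choose_roi_kind(
    mean_image: np.ndarray,
    center_um: tuple[float, float],
    nucleus_radius: float,
    soma_radius: float,
    pixel_size: float,
    dimming_threshold: float = 0.8,
) -> str:
    """Automate the annular-vs-circular choice from the time-average image.

    Returns ``"annular"`` when the central (would-be nucleus) mean is
    below ``dimming_threshold`` times the surrounding ring mean —
    i.e. the soma has a visibly dark center — else ``"circular"``.
    """
    size = mean_image.shape
    nuc = _disk_mask(center_um, nucleus_radius, 0.0, pixel_size, size)
    ring = _disk_mask(center_um, soma_radius, nucleus_radius, pixel_size, size)
    if not nuc.any() or not ring.any():
        return "circular"
    ring_mean = mean_image[ring].mean()
    if ring_mean <= 0:
        return "circular"
    return "annular" if mean_image[nuc].mean() < dimming_threshold * ring_mean else "circular"
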