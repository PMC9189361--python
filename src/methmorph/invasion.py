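"""Intrahepatic invasion-depth scoring.

Quantifies how deep tumor lesions have invaded a liver section from the
capsule surface where the cell-laden hydrogel drop was adhered.  The
relative invasion is RI = (deepest lesion extent from the capsule edge) /
(total liver depth), both measured in pixels along a declared axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["SectionMask", "InvasionResult", "mask_from_intensity", "relative_invasion"]

_CROSS = ndimage.generate_binary_structure(2, 1)


@dataclass
class SectionMask:
    """Liver and lesion masks of one stained section.

    ``invasion_axis`` declares the direction of invasion ('rows' means depth
    increases with row index); ``capsule_edge`` is the liver boundary side
    the hydrogel drop was adhered to ('start' = low index along the axis).
    """

    liver_mask: np.ndarray
    lesion_mask: np.ndarray
    invasion_axis: str = "rows"
    capsule_edge: str = "start"

    def __post_init__(self) -> None:
        self.liver_mask = np.asarray(self.liver_mask, dtype=bool)
        self.lesion_mask = np.asarray(self.lesion_mask, dtype=bool)
        if self.liver_mask.shape != self.lesion_mask.shape:
            raise ValueError("liver and lesion masks must share dimensions")
        if self.liver_mask.ndim != 2:
            raise ValueError("masks must be 2-D")
        if self.invasion_axis not in {"rows", "cols"}:
            raise ValueError("invasion_axis must be 'rows' or 'cols'")
        if self.capsule_edge not in {"start", "end"}:
            raise ValueError("capsule_edge must be 'start' or 'end'")
        if (self.lesion_mask & ~self.liver_mask).any():
            raise ValueError("lesion mask extends outside the liver mask")


@dataclass(frozen=True)
class InvasionResult:
    total_depth: int  # px
    invaded_depth: int  # px
    relative_invasion: float

    def __post_init__(self) -> None:
        if not (0 <= self.invaded_depth <= self.total_depth):
            raise ValueError("require 0 <= invaded_depth <= total_depth")


def mask_from_intensity(
    image: np.ndarray,
    threshold: float,
    polarity: str = "below",
    keep: str = "all",
) -> np.ndarray:
    """Threshold a grayscale image into a boolean mask.

    ``polarity`` 'below' keeps pixels <= threshold (dark stain on light
    background), 'above' keeps pixels >= threshold.  ``keep='largest'``
    retains only the largest 4-connected component (used for the liver
    outline); 'all' keeps every component (lesions may be multiple).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    if polarity == "below":
        mask = img <= threshold
    elif polarity == "above":
        mask = img >= threshold
    else:
        raise ValueError("polarity must be 'below' or 'above'")
    if not mask.any():
        raise ValueError("thresholding produced an empty mask")
    if keep == "largest":
        labels, n = ndimage.label(mask, structure=_CROSS)
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    elif keep != "all":
        raise ValueError("keep must be 'largest' or 'all'")
    return mask


def relative_invasion(section: SectionMask) -> InvasionResult:
    """Relative invasion RI = deepest lesion extent / total liver depth.

    Total depth is the maximum per-line extent of the liver along the
    invasion axis; invaded depth is the maximum distance of any lesion
    pixel from the capsule edge of the liver, measured per line (column or
    row) so an irregular capsule does not bias the depth origin.
    """
    liver = section.liver_mask
    lesion = section.lesion_mask
    if section.invasion_axis == "cols":
        liver, lesion = liver.T, lesion.T
    if section.capsule_edge == "end":
        liver, lesion = liver[::-1], lesion[::-1]
    if not liver.any():
        raise ValueError("liver mask is empty")

    n_rows = liver.shape[0]
    rows = np.arange(n_rows)[:, None]
    big = n_rows + 1
    first = np.where(liver.any(axis=0), np.where(liver, rows, big).min(axis=0), -1)
    last = np.where(liver.any(axis=0), np.where(liver, rows, -1).max(axis=0), -1)
    extents = np.where(first >= 0, last - first + 1, 0)
    total_depth = int(extents.max())

    if lesion.any():
        depth_map = np.where(lesion, rows - first[None, :] + 1, 0)
        invaded_depth = int(depth_map.max())
    else:
        invaded_depth = 0
    return InvasionResult(
        total_depth=total_depth,
        invaded_depth=invaded_depth,
        relative_invasion=invaded_depth / total_depth,
    )
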