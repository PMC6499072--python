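"""Low-level mask geometry shared by the generator and the measurement ops.

These are definitions (what "the IS band" or "the central contact arc" mean),
not measurements; both sides of every recovery test go through independent
image -> mask -> number paths.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi


def mask_centroid(mask: np.ndarray) -> np.ndarray:
    """Unweighted centroid of a binary mask, pixel coordinates."""
    coords = np.argwhere(mask)
    if coords.size == 0:
        raise ValueError("empty mask")
    return coords.mean(axis=0)


def weighted_centroid(weights: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Intensity-weighted centroid sum(w*p)/sum(w) over ``mask`` (or everywhere)."""
    w = np.asarray(weights, dtype=float)
    if mask is not None:
        w = np.where(mask, w, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("non-positive total weight")
    grids = np.indices(w.shape, dtype=float)
    return np.array([float((g * w).sum() / total) for g in grids])


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Boolean raster of mask pixels with at least one non-mask 8-neighbour."""
    struct = np.ones((3,) * mask.ndim, dtype=bool)
    return mask & ~ndi.binary_erosion(mask, structure=struct, border_value=0)


def contact_pixels(cell_mask: np.ndarray, other_mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Cell-boundary pixels within ``radius``-pixel dilation of the other mask.

    Returns an (n, ndim) integer coordinate array ordered along the contact
    (see :func:`order_along_segment`); empty array if there is no adjacency.
    """
    struct = np.ones((3,) * cell_mask.ndim, dtype=bool)
    near = ndi.binary_dilation(other_mask, structure=struct, iterations=radius)
    contact = boundary_pixels(cell_mask) & near
    coords = np.argwhere(contact)
    if len(coords) == 0:
        return coords
    return order_along_segment(coords)


def order_along_segment(coords: np.ndarray) -> np.ndarray:
    """Order a pixel set along its principal axis (stable for ties)."""
    coords = np.asarray(coords)
    if len(coords) < 2:
        return coords
    centered = coords - coords.mean(axis=0)
    # principal direction of the point set
    _, _, vt = np.linalg.svd(centered.astype(float), full_matrices=False)
    proj = centered @ vt[0]
    order = np.lexsort(tuple(coords[:, i] for i in range(coords.shape[1] - 1, -1, -1)) + (proj,))
    return coords[order]


def central_arc(contact: np.ndarray, fraction: float = 0.5) -> np.ndarray:
    """Central ``fraction`` of an ordered contact segment, by arc position."""
    n = len(contact)
    keep = max(1, int(round(n * fraction)))
    start = (n - keep) // 2
    return contact[start : start + keep]


def band_from_contact(
    cell_mask: np.ndarray, contact: np.ndarray, depth_px: float
) -> np.ndarray:
    """Cell pixels within ``depth_px`` (Euclidean) of any contact pixel."""
    seed = np.zeros(cell_mask.shape, dtype=bool)
    if len(contact):
        seed[tuple(contact.T)] = True
    dist = ndi.distance_transform_edt(~seed)
    return cell_mask & (dist <= depth_px)
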