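"""Face-on (en face) views of the contact and F-actin-depletion area metrics.

A z-stack is resliced along the cell-to-contact axis and maximum-projected
over a thin slab centered on the contact plane, giving a 2-D view of the
interface as seen from the T cell.  On that view the contact area is
delimited by the outer edge of the F-actin signal (threshold, largest
component, closing, hole fill) and the central F-actin-low region is the
largest contiguous sub-threshold patch whose centroid lies in the central
half-radius.  The area ratio scores a synapse "depleted" above the cutoff
(default 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import profile_line
from skimage.morphology import closing, disk

from .errors import (
    DegenerateRoiError,
    EmptyCohortError,
    InterfaceOutOfStackError,
    NoInterfaceSignalError,
)
from .roi import mask_centroid
from .scene import ImageScene
from .segmentation import ConjugateGeometry

DEFAULT_AREA_CUTOFF = 0.1
DEFAULT_LOW_FRACTION = 0.5  # low threshold as a fraction of the rim median
DEFAULT_SLAB_DEPTH_UM = 1.5


@dataclass
class InterfaceProjection:
    """Face-on raster plus contact / F-actin-low areas and the verdict."""

    faceon: np.ndarray = field(repr=False)
    is_region: np.ndarray = field(repr=False)
    low_region: np.ndarray = field(repr=False)
    is_area: float = 0.0  # um^2
    factin_low_area: float = 0.0  # um^2
    area_ratio: float = 0.0
    depleted: bool = False
    cutoff_used: float = DEFAULT_AREA_CUTOFF


def project_interface(
    stack: ImageScene,
    geometry: ConjugateGeometry,
    slab_depth_um: float = DEFAULT_SLAB_DEPTH_UM,
    role: str = "actin",
    t: int = 0,
) -> np.ndarray:
    """Max-project a slab normal to the IS axis, centered on the contact.

    The volume is sampled on an isotropic lateral-pixel grid (z rescaled by
    z_step/pixel_size, trilinear interpolation); when the IS axis is aligned
    with z this reduces exactly to a max projection of the corresponding
    z-substack.
    """
    if stack.n_planes < 3:
        raise InterfaceOutOfStackError("need a z-stack with >= 3 planes")
    if geometry.ndim != 3:
        raise InterfaceOutOfStackError("geometry must be 3-D to estimate the IS axis")
    vol = stack.volume(role, t)
    zs = stack.z_step / stack.pixel_size
    n = np.asarray(geometry.is_axis, dtype=float)
    # to physically-scaled (lateral-pixel) coordinates
    scale = np.array([zs, 1.0, 1.0])
    n_sc = n * scale
    n_sc /= np.linalg.norm(n_sc)
    center = np.asarray(geometry.is_centroid, dtype=float) * scale
    half = 0.5 * slab_depth_um / stack.pixel_size
    bounds = (np.array(vol.shape) - 1) * scale
    for s in (-half, half):
        p = center + s * n_sc
        if np.any(p < -0.5) or np.any(p > bounds + 0.5):
            raise InterfaceOutOfStackError("slab extends beyond the stack")

    if abs(n_sc[0]) > 0.999:  # axis along z: exact substack projection
        z0 = geometry.is_centroid[0]
        half_planes = 0.5 * slab_depth_um / stack.z_step
        lo = max(0, int(np.ceil(z0 - half_planes)))
        hi = min(vol.shape[0] - 1, int(np.floor(z0 + half_planes)))
        return vol[lo : hi + 1].max(axis=0)

    # orthonormal in-plane basis
    seed = np.zeros(3)
    seed[int(np.argmin(np.abs(n_sc)))] = 1.0
    u = np.cross(n_sc, seed)
    u /= np.linalg.norm(u)
    v = np.cross(n_sc, u)

    ny, nx = stack.shape_yx
    out_h = max(ny, int(np.ceil(bounds[0])) + 1)
    out_w = max(nx, int(np.ceil(bounds[0])) + 1)
    ii, jj = np.mgrid[0:out_h, 0:out_w].astype(float)
    di = ii - out_h / 2.0
    dj = jj - out_w / 2.0
    n_samples = max(3, int(np.ceil(2 * half)) + 1)
    offsets = np.linspace(-half, half, n_samples)
    faceon = np.full((out_h, out_w), -np.inf)
    for s in offsets:
        pts = center[:, None, None] + di * u[:, None, None] + dj * v[:, None, None] + s * n_sc[:, None, None]
        coords = pts / scale[:, None, None]  # back to array index space
        plane = ndi.map_coordinates(vol, coords, order=1, mode="constant", cval=0.0)
        faceon = np.maximum(faceon, plane)
    return faceon


def delimit_is_area(
    faceon: np.ndarray,
    pixel_size: float,
    closing_radius: int = 2,
    smooth_sigma_px: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Contact region enclosed by the outer F-actin edge, and its area in um^2.

    Light Gaussian smoothing, Otsu threshold, largest 8-connected component,
    morphological closing and hole filling (a bright annulus therefore yields
    the full filled disc).
    """
    if faceon.max() <= faceon.min():
        raise NoInterfaceSignalError("no above-threshold pixels on the face-on view")
    faceon = ndi.gaussian_filter(faceon, smooth_sigma_px) if smooth_sigma_px > 0 else faceon
    fg = faceon > threshold_otsu(faceon)
    if not fg.any():
        raise NoInterfaceSignalError("no above-threshold pixels on the face-on view")
    # When the foreground is itself strongly bimodal (dim cortical spill-over
    # around a bright rim), a second Otsu pass isolates the rim so the region
    # is delimited by the edge of the accumulated signal, not the spill-over.
    vals = faceon[fg]
    if vals.std() > 0.25 * vals.mean():
        fg2 = faceon > threshold_otsu(vals)
        if fg2.any():
            fg = fg2
    labels, nlab = ndi.label(fg, structure=np.ones((3, 3), dtype=bool))
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, nlab + 1))
    region = labels == (int(np.argmax(sizes)) + 1)
    region = closing(region, disk(closing_radius))
    region = ndi.binary_fill_holes(region)
    return region, float(region.sum()) * pixel_size**2


def factin_low_area(
    faceon: np.ndarray,
    is_region: np.ndarray,
    pixel_size: float,
    cutoff: float = DEFAULT_AREA_CUTOFF,
    low_fraction: float = DEFAULT_LOW_FRACTION,
    smooth_sigma_px: float = 1.0,
) -> InterfaceProjection:
    """Central F-actin-low area inside the contact region and its area ratio.

    The low threshold is ``low_fraction`` times the median intensity of the
    peripheral rim of the region (outermost ~15% of the equivalent radius);
    candidate low components must have their centroid within half the
    equivalent radius of the region centroid ("central"); the largest such
    component is taken.  Absence of any low region gives ratio 0.
    """
    if not is_region.any():
        raise NoInterfaceSignalError("empty contact region")
    smoothed = ndi.gaussian_filter(faceon, smooth_sigma_px) if smooth_sigma_px > 0 else faceon
    area_px = int(is_region.sum())
    r_eq = np.sqrt(area_px / np.pi)
    rim_w = max(2, int(round(0.15 * r_eq)))
    core = ndi.binary_erosion(is_region, structure=np.ones((3, 3), bool), iterations=rim_w)
    rim = is_region & ~core
    rim_median = float(np.median(smoothed[rim])) if rim.any() else float(np.median(smoothed[is_region]))
    thr = low_fraction * rim_median
    low_candidates = is_region & (smoothed < thr)
    center = mask_centroid(is_region)
    low_region = np.zeros_like(is_region)
    best_size = 0
    labels, nlab = ndi.label(low_candidates, structure=np.ones((3, 3), bool))
    for lab in range(1, nlab + 1):
        comp = labels == lab
        size = int(comp.sum())
        if size <= best_size:
            continue
        if np.linalg.norm(mask_centroid(comp) - center) <= 0.5 * r_eq:
            low_region = comp
            best_size = size
    ratio = best_size / area_px
    return InterfaceProjection(
        faceon=faceon,
        is_region=is_region,
        low_region=low_region,
        is_area=area_px * pixel_size**2,
        factin_low_area=best_size * pixel_size**2,
        area_ratio=float(ratio),
        depleted=ratio > cutoff,
        cutoff_used=cutoff,
    )


def intensity_profile(
    faceon: np.ndarray,
    start: tuple[float, float],
    end: tuple[float, float],
    linewidth: int = 1,
    pixel_size: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean intensity across a rectangular ROI's short axis, along its long axis.

    Returns (positions_um, values); positions start at 0 at ``start``.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    if np.linalg.norm(end - start) < 2.0:
        raise DegenerateRoiError("profile ROI shorter than 2 pixels")
    values = profile_line(
        faceon, start, end, linewidth=linewidth, order=1, mode="constant",
        reduce_func=np.mean,
    )
    positions = np.arange(values.size) * pixel_size
    return positions, values


def cohort_depletion(projections: list[InterfaceProjection]) -> float:
    """Percent (0-100) of synapses scored depleted; cutoffs must agree."""
    if not projections:
        raise EmptyCohortError("no interface projections")
    cutoffs = {p.cutoff_used for p in projections}
    if len(cutoffs) != 1:
        raise EmptyCohortError(f"mixed cutoffs in cohort: {sorted(cutoffs)}")
    return 100.0 * sum(p.depleted for p in projections) / len(projections)
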