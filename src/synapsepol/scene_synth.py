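"""Synthetic conjugate scene generator with machine-readable ground truth.

Renders two adjoining convex bodies (T cell + APC) with a flattened shared
contact, a punctate organelle cloud whose centroid is placed to realize a
requested polarization index, an actin channel with a parametric
burst-then-central-clearance temporal profile, optional PSF blur and
Poisson+Gaussian camera noise.  Every scene comes with a
:class:`~synapsepol.scene.GroundTruth` sidecar recorded before blur/noise, so
each measurement stage can be validated by parameter recovery.

Geometry is analytic: discs (2-D) or spheres (3-D) cut by a plane normal to
the cell-to-APC axis.  The contact plane sits between two pixel columns so the
two masks are disjoint while remaining 8-adjacent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .errors import SceneValidationError
from .roi import band_from_contact, central_arc, contact_pixels, mask_centroid
from .scene import GroundTruth, ImageScene

logger = logging.getLogger(__name__)

# rendered intensity levels (arbitrary camera units)
_APC_LEVEL = 100.0
_CELL_LEVEL = 80.0
_RIM_LEVEL = 140.0
_SHELL_LEVEL = 60.0
_FACET_RIM_LEVEL = 160.0
_FACET_LOW_FRACTION = 0.05  # central facet intensity as a fraction of the rim
_SPOT_AMPLITUDE = 150.0
_MTOC_AMPLITUDE = 250.0
_SPOT_SIGMA_PX = 1.2
_MTOC_SIGMA_PX = 1.5


@dataclass(frozen=True)
class ActinProfile:
    """Parametric temporal profile of cortical actin at the contact.

    The interface band intensity ratio rises from 1 to ``burst_amplitude``
    during ``[burst_start, burst_start + burst_duration)`` (minutes, half-open)
    and the central-band ratio is multiplied by ``1 - clearance_ratio`` during
    the clearance interval (defaults to the burst interval).
    """

    burst_start: float = 10.0
    burst_duration: float = 30.0
    burst_amplitude: float = 2.0
    clearance_ratio: float = 0.0
    clearance_start: float | None = None
    clearance_duration: float | None = None

    def validate(self) -> None:
        if self.burst_duration < 0:
            raise SceneValidationError("actin_profile.burst_duration", "must be >= 0")
        if self.burst_amplitude < 1:
            raise SceneValidationError("actin_profile.burst_amplitude", "must be >= 1")
        if not 0 <= self.clearance_ratio <= 1:
            raise SceneValidationError("actin_profile.clearance_ratio", "must be in [0, 1]")


@dataclass(frozen=True)
class SceneSpec:
    """Full parameterization of one synthetic scene (see module docstring).

    Physical sizes are um, times minutes, speeds um/s; ``shape_yx`` etc. are
    pixels/planes/frames.  A fixed ``seed`` gives byte-identical output.
    """

    seed: int = 0
    shape_yx: tuple[int, int] = (128, 128)
    n_z: int = 1
    n_t: int = 1
    pixel_size: float = 0.25
    z_step: float = 0.5
    frame_interval: float = 5.0
    cell_radius: float = 5.0
    apc_radius: float = 6.0
    true_pol_index: float = 0.0
    n_vesicles: int = 12
    vesicle_sigma: float = 1.0
    vesicle_min_spacing: float = 0.0
    actin_profile: ActinProfile = field(default_factory=ActinProfile)
    true_depletion_ratio: float = 0.0
    psf_sigma: float = 0.0
    poisson_scale: float = 0.0
    gaussian_sd: float = 0.0
    track_speed: float = 0.0
    track_diffusion: float = 0.0
    channel_corr: float = 0.0
    band_depth: float = 1.5
    central_fraction: float = 0.5
    drift_px: tuple[float, float] = (0.0, 0.0)

    def validate(self) -> None:
        pos = ("pixel_size", "z_step", "frame_interval", "cell_radius", "apc_radius")
        for name in pos:
            if getattr(self, name) <= 0:
                raise SceneValidationError(name, "must be > 0")
        nonneg = (
            "n_vesicles", "vesicle_sigma", "vesicle_min_spacing", "psf_sigma",
            "poisson_scale", "gaussian_sd", "track_speed", "track_diffusion",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise SceneValidationError(name, "must be >= 0")
        if not -1.0 <= self.true_pol_index <= 1.0:
            raise SceneValidationError("true_pol_index", "must be in [-1, 1]")
        if not 0.0 <= self.true_depletion_ratio <= 1.0:
            raise SceneValidationError("true_depletion_ratio", "must be in [0, 1]")
        if not -1.0 <= self.channel_corr <= 1.0:
            raise SceneValidationError("channel_corr", "must be in [-1, 1]")
        if not 0 < self.central_fraction <= 1:
            raise SceneValidationError("central_fraction", "must be in (0, 1]")
        if self.band_depth <= 0:
            raise SceneValidationError("band_depth", "must be > 0")
        if min(self.shape_yx) < 16:
            raise SceneValidationError("shape_yx", "must be at least 16 x 16")
        if self.n_z < 1 or self.n_t < 1:
            raise SceneValidationError("n_z", "axis lengths must be >= 1")
        self.actin_profile.validate()


# ---------------------------------------------------------------------------
# geometry construction
# ---------------------------------------------------------------------------

class _Bodies:
    """Analytic conjugate geometry in pixel space (2-D or 3-D)."""

    def __init__(self, spec: SceneSpec, center_shift: tuple[float, float] = (0.0, 0.0)):
        ny, nx = spec.shape_yx
        r1 = spec.cell_radius / spec.pixel_size
        r2 = spec.apc_radius / spec.pixel_size
        # 3-D cells are cut deeply (spread against the APC) so that within a
        # thin slab at the contact the cross-section barely exceeds the facet
        flat_frac = 0.15 if spec.n_z == 1 else 0.5
        flat1 = max(2.0, flat_frac * r1)
        flat2 = max(2.0, 0.15 * r2)
        self.xplane = int(round(nx * 0.52))  # contact between columns xplane, xplane+1
        cy = ny / 2.0 + center_shift[0]
        cx = self.xplane - (r1 - flat1) + center_shift[1]
        ax_ = self.xplane + 1 + (r2 - flat2)
        self.ndim = 2 if spec.n_z == 1 else 3
        self.zscale = spec.z_step / spec.pixel_size
        zc = (spec.n_z - 1) / 2.0
        if self.ndim == 2:
            yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
            d1 = (yy - cy) ** 2 + (xx - cx) ** 2
            d2 = (yy - cy) ** 2 + (xx - ax_) ** 2
            xgrid = xx
        else:
            zz, yy, xx = np.mgrid[0 : spec.n_z, 0:ny, 0:nx].astype(float)
            dz2 = ((zz - zc) * self.zscale) ** 2
            d1 = dz2 + (yy - cy) ** 2 + (xx - cx) ** 2
            d2 = dz2 + (yy - cy) ** 2 + (xx - ax_) ** 2
            xgrid = xx
        self.cell_mask = (d1 <= r1**2) & (xgrid <= self.xplane)
        self.apc_mask = (d2 <= r2**2) & (xgrid >= self.xplane + 1)
        if not self.cell_mask.any() or not self.apc_mask.any():
            raise SceneValidationError("cell_radius", "bodies do not fit in the image")
        self.dist_cell_sq = d1
        self.r1 = r1
        self.cell_center = np.array(([zc] if self.ndim == 3 else []) + [cy, cx])
        self.facet_radius = float(np.sqrt(max(r1**2 - (r1 - flat1) ** 2, 1.0)))
        self.contact = contact_pixels(self.cell_mask, self.apc_mask)
        if len(self.contact) == 0:
            raise SceneValidationError("apc_radius", "bodies do not touch")
        self.cell_centroid = mask_centroid(self.cell_mask)
        self.is_centroid = self.contact.mean(axis=0)
        axis = self.is_centroid - self.cell_centroid
        self.B = float(np.linalg.norm(axis))
        self.axis = axis / self.B

    def interior(self, margin_px: float) -> np.ndarray:
        struct = np.ones((3,) * self.ndim, dtype=bool)
        return ndi.binary_erosion(
            self.cell_mask, structure=struct, iterations=max(1, int(round(margin_px)))
        )


def _place_cloud(
    bodies: _Bodies,
    target: np.ndarray,
    n: int,
    sigma_px: float,
    rng: np.random.Generator,
    min_spacing_px: float = 0.0,
) -> np.ndarray:
    """Sample ``n`` spot centers inside the cell whose mean is exactly ``target``.

    ``min_spacing_px`` imposes a hard-core constraint (useful for fixtures
    that must resolve every punctum individually).
    """
    allowed = bodies.interior(2)
    if not allowed.any():
        allowed = bodies.cell_mask
    sigma = max(sigma_px, 1e-3)
    for _ in range(60):
        pts = np.empty((n, bodies.ndim))
        ok = True
        for i in range(n):
            for _try in range(200):
                p = target + rng.normal(0.0, sigma, size=bodies.ndim)
                idx = tuple(int(round(c)) for c in p)
                if not (all(0 <= idx[d] < allowed.shape[d] for d in range(bodies.ndim)) and allowed[idx]):
                    continue
                if min_spacing_px > 0 and i > 0 and (
                    np.linalg.norm(pts[:i] - p, axis=1).min() < min_spacing_px
                ):
                    continue
                pts[i] = p
                break
            else:
                ok = False
                break
        if ok:
            pts = pts + (target - pts.mean(axis=0))
            inside = all(
                bodies.cell_mask[tuple(np.clip(np.round(p).astype(int), 0, np.array(bodies.cell_mask.shape) - 1))]
                for p in pts
            )
            if inside:
                return pts
        sigma *= 0.7
    # degenerate fallback: pile every spot on the target
    return np.tile(target, (n, 1))


def _render_spots(shape: tuple, centers: np.ndarray, amplitude: float, sigma: float) -> np.ndarray:
    """Additive isotropic Gaussian spots on a zero raster (local windows)."""
    img = np.zeros(shape)
    half = int(np.ceil(4 * sigma))
    for c in np.atleast_2d(centers):
        lo = [max(0, int(np.floor(ci)) - half) for ci in c]
        hi = [min(s, int(np.ceil(ci)) + half + 1) for ci, s in zip(c, shape)]
        if any(l >= h for l, h in zip(lo, hi)):
            continue
        grids = np.meshgrid(*[np.arange(l, h, dtype=float) for l, h in zip(lo, hi)], indexing="ij")
        d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        img[tuple(slice(l, h) for l, h in zip(lo, hi))] += amplitude * np.exp(-d2 / (2 * sigma**2))
    return img


def _apply_optics_and_noise(
    data: np.ndarray, spec: SceneSpec, rng: np.random.Generator
) -> np.ndarray:
    """PSF blur then Poisson shot noise then additive Gaussian read noise."""
    out = data.astype(float)
    sig_xy = spec.psf_sigma / spec.pixel_size
    sig_z = spec.psf_sigma / spec.z_step
    for t in range(out.shape[0]):
        for c in range(out.shape[2]):
            vol = out[t, :, c]
            if spec.psf_sigma > 0:
                sigma = (sig_z, sig_xy, sig_xy) if vol.shape[0] > 1 else (0, sig_xy, sig_xy)
                vol = ndi.gaussian_filter(vol, sigma=sigma)
            if spec.poisson_scale > 0:
                vol = rng.poisson(np.clip(vol, 0, None) * spec.poisson_scale) / spec.poisson_scale
            if spec.gaussian_sd > 0:
                vol = vol + rng.normal(0.0, spec.gaussian_sd, size=vol.shape)
            out[t, :, c] = np.clip(vol, 0.0, None)
    return out


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def generate_conjugate_scene(spec: SceneSpec) -> tuple[ImageScene, GroundTruth]:
    """Render a static conjugate (single frame; 2-D or z-stack).

    Channels: 0 apc_dye, 1 actin, 2 organelle, 3 mtoc.  The organelle-cloud
    centroid is placed on the cell-to-IS axis at ``true_pol_index * B`` from
    the cell centroid, so the noise-free polarization index equals
    ``spec.true_pol_index`` exactly (the cloud mean is re-centered onto the
    target).  For z-stacks the actin facet carries a rim/central-depletion
    pattern realizing ``true_depletion_ratio``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    bodies = _Bodies(spec)
    ny, nx = spec.shape_yx
    shape = bodies.cell_mask.shape

    apc_ch = np.where(bodies.apc_mask, _APC_LEVEL, 0.0)
    actin_ch = _render_static_actin(bodies, spec)

    target = bodies.cell_centroid + spec.true_pol_index * bodies.B * bodies.axis
    # 3-D scenes carry a cytosolic fill in the organelle channel so the cell
    # body can be segmented independently of the facet-patterned actin
    organelle_ch = np.where(bodies.cell_mask, 1.5 * _CELL_LEVEL, 0.0) if bodies.ndim == 3 else np.zeros(shape)
    organelle_centroid = None
    vesicle_centers: list = []
    if spec.n_vesicles > 0:
        centers = _place_cloud(
            bodies, target, spec.n_vesicles, spec.vesicle_sigma / spec.pixel_size, rng,
            min_spacing_px=spec.vesicle_min_spacing / spec.pixel_size,
        )
        organelle_ch = organelle_ch + _render_spots(shape, centers, _SPOT_AMPLITUDE, _SPOT_SIGMA_PX)
        organelle_centroid = centers.mean(axis=0)
        vesicle_centers = centers.tolist()
    mtoc_ch = _render_spots(shape, target[None, :], _MTOC_AMPLITUDE, _MTOC_SIGMA_PX)

    stack = np.stack([apc_ch, actin_ch, organelle_ch, mtoc_ch])  # (c, [z,] y, x)
    if bodies.ndim == 2:
        data = stack[None, None]  # t, z
    else:
        data = stack.transpose(1, 0, 2, 3)[None]  # (t=1, z, c, y, x)
    data = _apply_optics_and_noise(data, spec, rng)
    scene = ImageScene(
        data=data,
        channel_roles={"apc_dye": 0, "actin": 1, "organelle": 2, "mtoc": 3},
        pixel_size=spec.pixel_size,
        z_step=spec.z_step,
        frame_interval=spec.frame_interval,
    )
    truth = GroundTruth(
        cell_mask=bodies.cell_mask,
        apc_mask=bodies.apc_mask,
        contact_segment=bodies.contact,
        cell_centroid=bodies.cell_centroid,
        is_centroid=bodies.is_centroid,
        organelle_centroid=organelle_centroid,
        mtoc_position=target,
        true_pol_index=spec.true_pol_index,
        true_depletion_ratio=spec.true_depletion_ratio if bodies.ndim == 3 else None,
        extras={"is_axis": bodies.axis.tolist(), "B_px": bodies.B,
                "facet_radius_px": bodies.facet_radius,
                "vesicle_centers": vesicle_centers},
    )
    return scene, truth


def _render_static_actin(bodies: _Bodies, spec: SceneSpec) -> np.ndarray:
    """Cortical rim + interior; 3-D facet carries the depletion pattern."""
    struct = np.ones((3,) * bodies.ndim, dtype=bool)
    interior = ndi.binary_erosion(bodies.cell_mask, structure=struct, iterations=2)
    rim = bodies.cell_mask & ~interior
    if bodies.ndim == 2:
        return np.where(rim, _RIM_LEVEL, 0.0) + np.where(interior, _CELL_LEVEL, 0.0)
    # 3-D: dim interior + closed dim shell, plus a facet *cylinder* thicker
    # than the default projection slab so the max projection inside the facet
    # radius sees only the rim/depletion pattern, never the interior
    actin = np.where(rim, _SHELL_LEVEL, 0.0) + np.where(interior, 0.3 * _CELL_LEVEL, 0.0)
    zz, yy, xx = np.indices(bodies.cell_mask.shape)
    zc, cy = bodies.cell_center[0], bodies.cell_center[1]
    r_facet = np.sqrt(((zz - zc) * bodies.zscale) ** 2 + (yy - cy) ** 2)
    depth_px = int(np.ceil(0.75 / spec.pixel_size)) + 3  # half default slab + margin
    facet = (
        bodies.cell_mask
        & (xx >= bodies.xplane - depth_px)
        & (r_facet <= bodies.facet_radius)
    )
    r_low = np.sqrt(spec.true_depletion_ratio) * bodies.facet_radius
    facet_val = np.where(r_facet < r_low, _FACET_LOW_FRACTION * _FACET_RIM_LEVEL, _FACET_RIM_LEVEL)
    actin[facet] = facet_val[facet]
    return actin


def generate_timelapse(spec: SceneSpec) -> tuple[ImageScene, GroundTruth]:
    """Render a 2-D time-lapse whose actin band ratios follow the profile.

    Per frame the mean-intensity ratios mean(IS band)/mean(cell) and
    mean(central band)/mean(IS band) equal the profile values exactly on the
    noise-free render; band intensities are solved analytically from the
    band/cell area fractions.  True per-frame ratios go to the ground truth.
    """
    spec.validate()
    if spec.n_t < 3:
        raise SceneValidationError("n_t", "time-lapse needs >= 3 frames")
    prof = spec.actin_profile
    span = spec.n_t * spec.frame_interval
    if prof.burst_start < 0 or prof.burst_start + prof.burst_duration > span:
        raise SceneValidationError(
            "actin_profile.burst_start", f"burst interval outside the time axis (0..{span} min)"
        )
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.shape_yx
    if spec.n_z != 1:
        raise SceneValidationError("n_z", "time-lapse generator renders 2-D frames only")

    c_start = prof.clearance_start if prof.clearance_start is not None else prof.burst_start
    c_dur = prof.clearance_duration if prof.clearance_duration is not None else prof.burst_duration

    times = np.arange(spec.n_t) * spec.frame_interval
    ratio_is_cell = np.where(
        (times >= prof.burst_start) & (times < prof.burst_start + prof.burst_duration),
        prof.burst_amplitude, 1.0,
    )
    ratio_cis_is = np.where(
        (times >= c_start) & (times < c_start + c_dur), 1.0 - prof.clearance_ratio, 1.0
    )

    frames = []
    contact_centroids = []
    bodies0 = None
    band_px = spec.band_depth / spec.pixel_size
    for k in range(spec.n_t):
        shift = (spec.drift_px[0] * k, spec.drift_px[1] * k)
        bodies = _Bodies(spec, center_shift=shift)
        if bodies0 is None:
            bodies0 = bodies
        is_band = band_from_contact(bodies.cell_mask, bodies.contact, band_px)
        cis_band = band_from_contact(
            bodies.cell_mask, central_arc(bodies.contact, spec.central_fraction), band_px
        ) & is_band
        actin = _solve_band_intensities(
            bodies.cell_mask, is_band, cis_band, float(ratio_is_cell[k]), float(ratio_cis_is[k])
        )
        apc_ch = np.where(bodies.apc_mask, _APC_LEVEL, 0.0)
        # cytosolic fill: lets callers segment the cell independently of the
        # (burst-modulated, multi-modal) actin channel
        organelle_ch = np.where(bodies.cell_mask, 1.5 * _CELL_LEVEL, 0.0)
        frames.append(np.stack([apc_ch, actin, organelle_ch]))
        contact_centroids.append(bodies.contact.mean(axis=0))

    data = np.stack(frames)[:, None]  # (t, z=1, c, y, x)
    data = _apply_optics_and_noise(data, spec, rng)
    scene = ImageScene(
        data=data,
        channel_roles={"apc_dye": 0, "actin": 1, "organelle": 2},
        pixel_size=spec.pixel_size,
        z_step=spec.z_step,
        frame_interval=spec.frame_interval,
    )
    truth = GroundTruth(
        cell_mask=bodies0.cell_mask,
        apc_mask=bodies0.apc_mask,
        contact_segment=bodies0.contact,
        cell_centroid=bodies0.cell_centroid,
        is_centroid=bodies0.is_centroid,
        true_ratio_is_cell=ratio_is_cell,
        true_ratio_cis_is=ratio_cis_is,
        extras={
            "burst_start": prof.burst_start,
            "burst_duration": prof.burst_duration,
            "burst_amplitude": prof.burst_amplitude,
            "clearance_ratio": prof.clearance_ratio,
            "contact_centroids": np.asarray(contact_centroids).tolist(),
        },
    )
    return scene, truth


def _solve_band_intensities(
    cell: np.ndarray, is_band: np.ndarray, cis_band: np.ndarray, a: float, c: float
) -> np.ndarray:
    """Fill the cell with intensities so mean(IS)/mean(cell)=a, mean(cIS)/mean(IS)=c.

    With band/cell area fraction f and central/band fraction h the required
    band mean is s = a*I0*(1-f)/(1-a*f) and the central/peripheral intensity
    ratio g solves c = g/(1-h+g*h).
    """
    i0 = _CELL_LEVEL
    f = is_band.sum() / cell.sum()
    h = cis_band.sum() / max(is_band.sum(), 1)
    if a * f >= 1:
        raise SceneValidationError("actin_profile.burst_amplitude", "amplitude*band_fraction >= 1")
    s = a * i0 * (1 - f) / (1 - a * f)
    denom = 1 - c * h
    g = c * (1 - h) / denom if denom > 0 else 0.0
    x = s / (1 - h + g * h)
    actin = np.where(cell, i0, 0.0)
    actin[is_band] = x
    actin[cis_band] = g * x
    return actin


def generate_vesicle_frames(spec: SceneSpec) -> tuple[ImageScene, GroundTruth]:
    """Render drifting (plus optional diffusing) spots for tracking tests.

    Each of ``n_vesicles`` spots moves along a per-spot random direction at
    ``track_speed`` um/s, with an optional per-frame Gaussian jitter of
    ``track_diffusion`` um; true positions per frame are recorded.
    """
    spec.validate()
    if spec.n_t < 2:
        raise SceneValidationError("n_t", "tracking fixture needs >= 2 frames")
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.shape_yx
    step_px = spec.track_speed * spec.frame_interval * 60.0 / spec.pixel_size
    diff_px = spec.track_diffusion / spec.pixel_size
    n = max(spec.n_vesicles, 1)
    margin = 6 + step_px * spec.n_t
    lo = np.array([margin, margin])
    hi = np.array([ny - margin, nx - margin])
    if np.any(hi <= lo):
        raise SceneValidationError("track_speed", "tracks would leave the image; shrink speed/frames")
    starts = rng.uniform(lo, hi, size=(n, 2))
    theta = rng.uniform(0, 2 * np.pi, size=n)
    dirs = np.stack([np.sin(theta), np.cos(theta)], axis=1)

    if n > 1:
        d = np.linalg.norm(starts[:, None] - starts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 2 * _SPOT_SIGMA_PX:
            logger.warning("spot spacing %.2f px below linking resolution", d.min())

    positions = np.empty((n, spec.n_t, 2))
    positions[:, 0] = starts
    for k in range(1, spec.n_t):
        jitter = rng.normal(0.0, diff_px, size=(n, 2)) if diff_px > 0 else 0.0
        positions[:, k] = positions[:, k - 1] + step_px * dirs + jitter
    frames = [
        _render_spots((ny, nx), positions[:, k], _SPOT_AMPLITUDE, _SPOT_SIGMA_PX)[None]
        for k in range(spec.n_t)
    ]
    data = np.stack(frames)[:, None]  # (t, z, c=1, y, x)
    data = _apply_optics_and_noise(data, spec, rng)
    scene = ImageScene(
        data=data,
        channel_roles={"organelle": 0},
        pixel_size=spec.pixel_size,
        z_step=spec.z_step,
        frame_interval=spec.frame_interval,
    )
    empty = np.zeros((ny, nx), dtype=bool)
    truth = GroundTruth(
        cell_mask=empty,
        apc_mask=empty,
        contact_segment=np.empty((0, 2), dtype=int),
        cell_centroid=np.array([ny / 2, nx / 2]),
        is_centroid=np.array([ny / 2, nx / 2]),
        track_positions=positions,
        track_speed_um_s=spec.track_speed,
    )
    return scene, truth


def generate_correlated_channels(
    rho: float, n_pixels: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two nonnegative intensity vectors with population Pearson correlation rho.

    Bivariate-Gaussian pairs are shifted/scaled per channel (a positive affine
    map, which leaves the sample Pearson coefficient untouched).
    """
    if not -1.0 <= rho <= 1.0:
        raise SceneValidationError("rho", "must be in [-1, 1]")
    if n_pixels < 2:
        raise SceneValidationError("n_pixels", "must be >= 2")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n_pixels)
    if abs(rho) == 1.0:
        z2 = np.sign(rho) * z1
    else:
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n_pixels)

    def to_intensity(z: np.ndarray) -> np.ndarray:
        span = np.ptp(z)
        return (z - z.min()) * (200.0 / span if span > 0 else 1.0)

    return to_intensity(z1), to_intensity(z2)


def save_scene(scene: ImageScene, truth: GroundTruth, stem: str) -> None:
    """Write ``<stem>.ome.tif`` plus truth/label sidecars."""
    scene.write_ome_tiff(f"{stem}.ome.tif")
    truth.write_sidecars(stem)


def with_seed(spec: SceneSpec, seed: int) -> SceneSpec:
    """Copy of ``spec`` with a different seed."""
    return replace(spec, seed=seed)
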