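"""Multi-channel image container and TIFF I/O.

The canonical in-memory layout is a 5-D array with axes ``(t, z, c, y, x)``
(any axis may be singleton), matching the OME axis order TZCYX used on disk.
Coordinates throughout the package are 0-based ``(y, x)`` (or ``(z, y, x)``)
with pixel centers at integer positions; physical calibration is carried
separately (``pixel_size`` in um/pixel, ``z_step`` in um, ``frame_interval``
in minutes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import SceneValidationError

#: Channel roles the pipeline understands.
KNOWN_ROLES = ("apc_dye", "actin", "organelle", "mtoc", "sensor")


@dataclass
class ImageScene:
    """An intensity raster with declared channel roles and calibration.

    Attributes
    ----------
    data:
        ``float64`` array of shape ``(t, z, c, y, x)``; intensities >= 0.
    channel_roles:
        Mapping from role name (see :data:`KNOWN_ROLES`) to channel index.
    pixel_size:
        Lateral calibration, um/pixel (> 0).
    z_step:
        Axial spacing, um (> 0).
    frame_interval:
        Time between frames, minutes (> 0).
    """

    data: np.ndarray
    channel_roles: dict[str, int]
    pixel_size: float
    z_step: float = 1.0
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 5:
            raise SceneValidationError("data", "expected a 5-D (t, z, c, y, x) array")
        if np.any(self.data < 0):
            raise SceneValidationError("data", "intensities must be >= 0")
        if self.pixel_size <= 0:
            raise SceneValidationError("pixel_size", "must be > 0")
        if self.z_step <= 0:
            raise SceneValidationError("z_step", "must be > 0")
        if self.frame_interval <= 0:
            raise SceneValidationError("frame_interval", "must be > 0")
        n_c = self.data.shape[2]
        for role, idx in self.channel_roles.items():
            if role not in KNOWN_ROLES:
                raise SceneValidationError("channel_roles", f"unknown role {role!r}")
            if not 0 <= idx < n_c:
                raise SceneValidationError(
                    "channel_roles", f"role {role!r} maps to channel {idx} outside 0..{n_c - 1}"
                )

    # -- axis helpers ------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_planes(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[3], self.data.shape[4]

    def has_role(self, role: str) -> bool:
        return role in self.channel_roles

    def plane(self, role: str, t: int = 0, z: int = 0) -> np.ndarray:
        """Return a single 2-D (y, x) plane for a channel role."""
        return self.data[t, z, self.channel_roles[role]]

    def volume(self, role: str, t: int = 0) -> np.ndarray:
        """Return the 3-D (z, y, x) stack for a channel role at one frame."""
        return self.data[t, :, self.channel_roles[role]]

    def frame_times(self) -> np.ndarray:
        """Frame acquisition times in minutes, starting at 0."""
        return np.arange(self.n_frames, dtype=float) * self.frame_interval

    # -- calibration -------------------------------------------------------
    def px_to_um(self, coords_px: np.ndarray) -> np.ndarray:
        """Convert pixel (y, x) or (z, y, x) coordinates to um (anisotropic z)."""
        coords_px = np.asarray(coords_px, dtype=float)
        scale = np.full(coords_px.shape[-1], self.pixel_size)
        if coords_px.shape[-1] == 3:
            scale[0] = self.z_step
        return coords_px * scale

    def um_to_px(self, coords_um: np.ndarray) -> np.ndarray:
        coords_um = np.asarray(coords_um, dtype=float)
        scale = np.full(coords_um.shape[-1], self.pixel_size)
        if coords_um.shape[-1] == 3:
            scale[0] = self.z_step
        return coords_um / scale

    # -- I/O ---------------------------------------------------------------
    def write_ome_tiff(self, path: str | Path) -> None:
        """Write an OME-TIFF (axes TZCYX); channel roles become channel names."""
        n_c = self.data.shape[2]
        names = ["" for _ in range(n_c)]
        for role, idx in self.channel_roles.items():
            names[idx] = role
        names = [n or f"C{i}" for i, n in enumerate(names)]
        tifffile.imwrite(
            str(path),
            self.data.astype(np.float32),
            ome=True,
            metadata={
                "axes": "TZCYX",
                "PhysicalSizeX": self.pixel_size, "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": self.pixel_size, "PhysicalSizeYUnit": "µm",
                "PhysicalSizeZ": self.z_step, "PhysicalSizeZUnit": "µm",
                "TimeIncrement": self.frame_interval, "TimeIncrementUnit": "min",
                "Channel": {"Name": names},
            },
        )

    @classmethod
    def read_tiff(
        cls,
        path: str | Path,
        channel_roles: dict[str, int] | None = None,
        pixel_size: float | None = None,
        z_step: float | None = None,
        frame_interval: float | None = None,
    ) -> "ImageScene":
        """Read a TIFF written by :meth:`write_ome_tiff` (or any TZCYX stack).

        OME metadata (physical sizes, time increment, channel names matching
        known roles) supplies defaults; explicit arguments override it, which
        is needed for third-party files without such tags.
        """
        with tifffile.TiffFile(str(path)) as tif:
            series = tif.series[0]
            arr = series.asarray()
            axes = series.axes
            meta = _parse_ome_metadata(tif.ome_metadata) if tif.is_ome else {}
        arr = _expand_to_tzcyx(arr, axes)
        roles = channel_roles if channel_roles is not None else meta.get("channel_roles")
        if roles is None:
            raise SceneValidationError("channel_roles", "not in file metadata and not provided")
        return cls(
            data=arr,
            channel_roles={k: int(v) for k, v in roles.items()},
            pixel_size=float(pixel_size if pixel_size is not None else meta.get("pixel_size", 1.0)),
            z_step=float(z_step if z_step is not None else meta.get("z_step", 1.0)),
            frame_interval=float(
                frame_interval if frame_interval is not None else meta.get("frame_interval", 1.0)
            ),
        )


def _parse_ome_metadata(xml: str | None) -> dict:
    """Extract calibration and role-named channels from OME-XML."""
    if not xml:
        return {}
    import xml.etree.ElementTree as ET

    try:
        root = ET.fromstring(xml)
    except ET.ParseError:
        return {}
    pixels = next((el for el in root.iter() if el.tag.endswith("Pixels")), None)
    if pixels is None:
        return {}
    meta: dict = {}
    if pixels.get("PhysicalSizeX"):
        meta["pixel_size"] = float(pixels.get("PhysicalSizeX"))
    if pixels.get("PhysicalSizeZ"):
        meta["z_step"] = float(pixels.get("PhysicalSizeZ"))
    if pixels.get("TimeIncrement"):
        meta["frame_interval"] = float(pixels.get("TimeIncrement"))
    names = [el.get("Name") for el in pixels if el.tag.endswith("Channel")]
    roles = {n: i for i, n in enumerate(names) if n in KNOWN_ROLES}
    if roles:
        meta["channel_roles"] = roles
    return meta


def _expand_to_tzcyx(arr: np.ndarray, axes: str) -> np.ndarray:
    """Reorder/expand an array with OME-style axis labels to (t, z, c, y, x)."""
    axes = axes.upper().replace("S", "C").replace("Q", "T")
    if arr.ndim == 2:
        return arr[None, None, None]
    want = "TZCYX"
    for ax in axes:
        if ax not in want:
            raise SceneValidationError("data", f"unsupported axis {ax!r} in TIFF")
    # insert missing singleton axes, then transpose to canonical order
    for ax in want:
        if ax not in axes:
            arr = np.expand_dims(arr, axis=0)
            axes = ax + axes
    order = [axes.index(ax) for ax in want]
    return np.transpose(arr, order)


@dataclass
class GroundTruth:
    """Machine-readable truth emitted next to every synthetic scene.

    All coordinates are pixels, (y, x) or (z, y, x), recorded *before* blur
    and noise were applied; calibration lives on the paired scene.
    """

    cell_mask: np.ndarray
    apc_mask: np.ndarray
    contact_segment: np.ndarray  # (n, ndim) pixel coordinates
    cell_centroid: np.ndarray
    is_centroid: np.ndarray
    organelle_centroid: np.ndarray | None = None
    mtoc_position: np.ndarray | None = None
    true_pol_index: float | None = None
    true_depletion_ratio: float | None = None
    true_ratio_is_cell: np.ndarray | None = None  # per frame
    true_ratio_cis_is: np.ndarray | None = None  # per frame
    track_positions: np.ndarray | None = None  # (n_tracks, n_frames, 2) px
    track_speed_um_s: float | None = None
    extras: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v

        out = {}
        for k in (
            "contact_segment",
            "cell_centroid",
            "is_centroid",
            "organelle_centroid",
            "mtoc_position",
            "true_pol_index",
            "true_depletion_ratio",
            "true_ratio_is_cell",
            "true_ratio_cis_is",
            "track_positions",
            "track_speed_um_s",
            "extras",
        ):
            v = getattr(self, k)
            if v is not None:
                out[k] = conv(v)
        return out

    def write_sidecars(self, stem: str | Path) -> None:
        """Write ``<stem>.truth.json`` and ``<stem>.labels.tif``.

        The label raster encodes 1 = T cell, 2 = APC.
        """
        import json

        stem = Path(stem)
        labels = np.zeros(self.cell_mask.shape, dtype=np.uint8)
        labels[self.cell_mask] = 1
        labels[self.apc_mask] = 2
        tifffile.imwrite(str(stem) + ".labels.tif", labels)
        with open(str(stem) + ".truth.json", "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)
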