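"""Time-resolved actin reorganization at the contact, from floating ROIs.

Per frame three nested ROIs are derived from the segmented conjugate: the
whole T cell, an interface band of configurable depth inward from the contact
segment, and a central band built on the central fraction of the contact arc.
The two mean-intensity ratios (interface/cell and central/interface) drive
the interval summaries: the reorganization interval is the longest contiguous
run of interface/cell ratio strictly above 1 + delta, the depletion interval
the longest run of central/interface ratio below 1 - delta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    NoConjugateError,
    NoCellError,
    UnstableConjugateError,
    ZeroBaselineError,
)
from .roi import band_from_contact, central_arc
from .scene import ImageScene
from .segmentation import ConjugateGeometry, SegmentationConfig, segment_conjugate

logger = logging.getLogger(__name__)

DEFAULT_RATIO_DELTA = 0.05
DEFAULT_BAND_DEPTH_UM = 1.5
DEFAULT_CENTRAL_FRACTION = 0.5


@dataclass
class RoiSeries:
    """Per-frame cell / interface / central masks and their mean intensities."""

    cell_masks: list = field(repr=False)
    is_masks: list = field(repr=False)
    cis_masks: list = field(repr=False)
    mean_cell: np.ndarray = None
    mean_is: np.ndarray = None
    mean_cis: np.ndarray = None
    times_min: np.ndarray = None
    propagated: np.ndarray = None  # True where segmentation failed and masks were copied


@dataclass
class ActinKinetics:
    """Framewise ratio series plus interval/peak summaries."""

    ratio_is_cell: np.ndarray
    ratio_cis_is: np.ndarray
    times_min: np.ndarray
    frame_interval: float
    reorganization_duration: float = 0.0
    peak_time: float = float("nan")
    max_ratio_is_cell: float = float("nan")
    depletion_present: bool = False
    depletion_duration: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times_min,
                "ratio_is_cell": self.ratio_is_cell,
                "ratio_cis_is": self.ratio_cis_is,
            }
        )


def extract_floating_rois(
    timelapse: ImageScene,
    band_depth_um: float = DEFAULT_BAND_DEPTH_UM,
    central_fraction: float = DEFAULT_CENTRAL_FRACTION,
    config: SegmentationConfig | None = None,
    max_lost_fraction: float = 0.2,
) -> RoiSeries:
    """Re-segment every frame and build the three nested ROIs per frame.

    Frames where segmentation fails inherit the masks of the nearest
    successfully segmented frame and are flagged in ``propagated``.  If more
    than ``max_lost_fraction`` of frames fail, ``UnstableConjugateError``.
    """
    n_t = timelapse.n_frames
    if n_t < 3:
        raise UnstableConjugateError("need at least 3 frames")
    band_px = band_depth_um / timelapse.pixel_size
    geoms: list[ConjugateGeometry | None] = []
    for t in range(n_t):
        try:
            geoms.append(segment_conjugate(timelapse, t=t, config=config))
        except (NoConjugateError, NoCellError):
            geoms.append(None)
    lost = [i for i, g in enumerate(geoms) if g is None]
    if len(lost) > max_lost_fraction * n_t:
        raise UnstableConjugateError(f"conjugate lost in {len(lost)}/{n_t} frames")
    good = [i for i, g in enumerate(geoms) if g is not None]
    if not good:
        raise UnstableConjugateError("no frame segmentable")
    for i in lost:
        nearest = min(good, key=lambda j: abs(j - i))
        geoms[i] = geoms[nearest]
        logger.warning("frame %d: segmentation failed; masks propagated from frame %d", i, nearest)

    actin_idx = timelapse.channel_roles["actin"]
    cell_masks, is_masks, cis_masks = [], [], []
    mean_cell = np.empty(n_t)
    mean_is = np.empty(n_t)
    mean_cis = np.empty(n_t)
    for t, g in enumerate(geoms):
        cell = g.t_cell_mask
        is_band = band_from_contact(cell, g.contact_segment, band_px)
        cis_band = band_from_contact(cell, central_arc(g.contact_segment, central_fraction), band_px)
        cis_band &= is_band
        img = timelapse.data[t, 0, actin_idx]
        cell_masks.append(cell)
        is_masks.append(is_band)
        cis_masks.append(cis_band)
        mean_cell[t] = img[cell].mean() if cell.any() else np.nan
        mean_is[t] = img[is_band].mean() if is_band.any() else np.nan
        mean_cis[t] = img[cis_band].mean() if cis_band.any() else np.nan
    flags = np.zeros(n_t, dtype=bool)
    flags[lost] = True
    return RoiSeries(
        cell_masks=cell_masks,
        is_masks=is_masks,
        cis_masks=cis_masks,
        mean_cell=mean_cell,
        mean_is=mean_is,
        mean_cis=mean_cis,
        times_min=timelapse.frame_times(),
        propagated=flags,
    )


def actin_ratio_series(series: RoiSeries, delta: float = DEFAULT_RATIO_DELTA) -> ActinKinetics:
    """Framewise interface/cell and central/interface ratios plus summaries.

    Zero-denominator frames yield NaN ratios (excluded from runs) with a
    warning.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        r_ic = np.where(series.mean_cell > 0, series.mean_is / series.mean_cell, np.nan)
        r_ci = np.where(series.mean_is > 0, series.mean_cis / series.mean_is, np.nan)
    for name, r in (("IS/cell", r_ic), ("cIS/IS", r_ci)):
        bad = np.flatnonzero(~np.isfinite(r))
        if bad.size:
            logger.warning("%s ratio undefined at frames %s (zero denominator)", name, bad.tolist())
    if len(series.times_min) > 1:
        frame_interval = float(np.diff(series.times_min).mean())
    else:
        frame_interval = float("nan")
    kin = ActinKinetics(
        ratio_is_cell=r_ic,
        ratio_cis_is=r_ci,
        times_min=series.times_min,
        frame_interval=frame_interval,
    )
    dur, peak_t, max_r = reorganization_interval(kin, delta)
    kin.reorganization_duration = dur
    kin.peak_time = peak_t
    kin.max_ratio_is_cell = max_r
    present, ddur = depletion_interval(kin, delta)
    kin.depletion_present = present
    kin.depletion_duration = ddur
    return kin


def _longest_run(flags: np.ndarray) -> tuple[int, int]:
    """(start, length) of the longest contiguous True run; (-1, 0) if none."""
    best_start, best_len = -1, 0
    start = None
    for i, f in enumerate(list(flags) + [False]):
        if f and start is None:
            start = i
        elif not f and start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    return best_start, best_len


def reorganization_interval(
    kinetics: ActinKinetics, delta: float = DEFAULT_RATIO_DELTA
) -> tuple[float, float, float]:
    """Duration (min), peak time and max ratio of the longest run above 1 + delta.

    Duration counts frames in the run times the frame interval; an all-below
    series returns duration 0 with the global maximum as ``max_ratio``.
    """
    r = kinetics.ratio_is_cell
    finite = np.isfinite(r)
    above = finite & (r > 1.0 + delta)
    start, length = _longest_run(above)
    if length == 0:
        max_r = float(np.nanmax(r)) if finite.any() else float("nan")
        return 0.0, float("nan"), max_r
    run = slice(start, start + length)
    peak_local = int(np.nanargmax(r[run]))
    return (
        length * kinetics.frame_interval,
        float(kinetics.times_min[start + peak_local]),
        float(r[run][peak_local]),
    )


def depletion_interval(
    kinetics: ActinKinetics, delta: float = DEFAULT_RATIO_DELTA
) -> tuple[bool, float]:
    """Presence and duration (min) of the longest run of cIS/IS below 1 - delta."""
    r = kinetics.ratio_cis_is
    below = np.isfinite(r) & (r < 1.0 - delta)
    _, length = _longest_run(below)
    duration = length * kinetics.frame_interval
    return duration > 0, duration


def sensor_fi_ratio(
    fi_series: np.ndarray, times_min: np.ndarray, baseline_time: float
) -> np.ndarray:
    """FI[t] / FI[baseline frame]; the baseline frame is the one at
    ``baseline_time`` minutes (nearest grid point within half an interval)."""
    fi = np.asarray(fi_series, dtype=float)
    times = np.asarray(times_min, dtype=float)
    if fi.shape != times.shape or fi.size == 0:
        raise ZeroBaselineError("FI series and times must be same nonempty length")
    idx = int(np.argmin(np.abs(times - baseline_time)))
    if times.size > 1:
        half = 0.5 * float(np.diff(times).mean())
        if abs(times[idx] - baseline_time) > half:
            raise ZeroBaselineError(f"no frame at baseline time {baseline_time} min")
    if fi[idx] <= 0:
        raise ZeroBaselineError("baseline FI is zero")
    return fi / fi[idx]


def residence_half_life(
    fi_series: np.ndarray, times_min: np.ndarray
) -> tuple[float, bool]:
    """Time from the FI peak to the half-way level toward the final baseline.

    The level is baseline + 0.5*(peak - baseline) with baseline the final
    value of the series; the crossing is linearly interpolated between frames.
    Returns (half_life_min, censored); censored when the series never decays
    (flat or rising after the peak).
    """
    fi = np.asarray(fi_series, dtype=float)
    times = np.asarray(times_min, dtype=float)
    if fi.size < 2:
        return float("nan"), True
    peak = int(np.argmax(fi))
    baseline = fi[-1]
    amplitude = fi[peak] - baseline
    span = float(times[-1] - times[peak])
    if amplitude <= 0 or peak == fi.size - 1:
        return span, True
    level = baseline + 0.5 * amplitude
    for i in range(peak + 1, fi.size):
        if fi[i] <= level:
            f0, f1 = fi[i - 1], fi[i]
            t0, t1 = times[i - 1], times[i]
            frac = (f0 - level) / (f0 - f1) if f0 != f1 else 1.0
            return float(t0 + frac * (t1 - t0) - times[peak]), False
    return span, True
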