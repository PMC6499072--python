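"""Signed, size-normalized organelle polarization index and cohort statistics.

The index is the ratio A/B where B is the distance from the cell centroid to
the contact (IS) centroid and A is the signed scalar projection of the
organelle-centroid displacement onto the cell-to-IS axis (negative away from
the synapse).  A/B ranges from +1 to -1 for centroids inside the cell and is
clamped to that interval; a conjugate is scored "polarized" when the index
strictly exceeds the cutoff (default 0.25).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, EmptyCohortError, UndefinedCorrelationError
from .segmentation import ConjugateGeometry

DEFAULT_POL_CUTOFF = 0.25


@dataclass(frozen=True)
class PolarizationResult:
    """A (um, signed), B (um, > 0), clamped index, raw ratio, and the verdict."""

    A: float
    B: float
    pol_index: float
    raw_ratio: float
    organelle: str
    polarized: bool
    cutoff_used: float


def polarization_index(
    geometry: ConjugateGeometry,
    organelle_centroid_px: np.ndarray,
    organelle: str = "MVB",
    cutoff: float = DEFAULT_POL_CUTOFF,
    reference: str = "is_centroid",
) -> PolarizationResult:
    """Compute the polarization index for one conjugate.

    Distances are evaluated in um (anisotropic z handled by calibration), but
    the ratio itself is invariant to uniform coordinate scaling.

    ``reference`` selects the synapse reference point: ``"is_centroid"``
    (default; axis through the contact-segment centroid) or
    ``"nearest_contact"`` (axis through the contact pixel closest to the
    organelle centroid — an alternative reading, offered without
    endorsement).

    Raises ``DegenerateGeometryError`` when the cell centroid coincides with
    the reference point (B = 0).
    """
    cell_um = geometry.cell_centroid_um
    org_um = geometry.to_um(organelle_centroid_px)
    if reference == "is_centroid":
        is_um = geometry.is_centroid_um
    elif reference == "nearest_contact":
        contact_um = geometry.to_um(geometry.contact_segment)
        nearest = int(np.argmin(np.linalg.norm(contact_um - org_um, axis=1)))
        is_um = contact_um[nearest]
    else:
        raise ValueError(f"unknown reference {reference!r}")
    axis = is_um - cell_um
    B = float(np.linalg.norm(axis))
    if B == 0:
        raise DegenerateGeometryError("cell centroid lies on the IS centroid")
    axis = axis / B
    A = float(np.dot(org_um - cell_um, axis))
    raw = A / B
    idx = float(np.clip(raw, -1.0, 1.0))
    return PolarizationResult(
        A=A, B=B, pol_index=idx, raw_ratio=raw, organelle=organelle,
        polarized=idx > cutoff, cutoff_used=cutoff,
    )


def cohort_polarization(results: list[PolarizationResult]) -> float:
    """Percent (0-100) of conjugates scored polarized; cutoffs must agree."""
    if not results:
        raise EmptyCohortError("no polarization results")
    cutoffs = {r.cutoff_used for r in results}
    if len(cutoffs) != 1:
        raise EmptyCohortError(f"mixed cutoffs in cohort: {sorted(cutoffs)}")
    return 100.0 * sum(r.polarized for r in results) / len(results)


def mvb_mtoc_correlation(
    mvb: list[PolarizationResult], mtoc: list[PolarizationResult]
) -> float:
    """Pearson product-moment correlation of paired MVB vs MTOC indexes."""
    if len(mvb) != len(mtoc) or len(mvb) < 3:
        raise UndefinedCorrelationError("need >= 3 paired results")
    x = np.array([r.pol_index for r in mvb])
    y = np.array([r.pol_index for r in mtoc])
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance in one organelle's indexes")
    return float(np.corrcoef(x, y)[0, 1])
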