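"""Cubic volume-of-interest selection inside a femoral head, plus QC rules.

The VOI is an axis-aligned cube centred on the *central slice* — the plane
splitting the head into a distal and a proximal half — grown as large as
possible without touching cortical bone.  Its physical edge length ``vl``
doubles as the body-size proxy in the comparative analyses.  Specimens are
flagged (not deleted) when the scan resolution or the absolute connectivity
is too low for reliable morphometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .morphometry import MorphometrySummary
from .volume import BinaryVolume

__all__ = [
    "HeadMask",
    "VOISpec",
    "QCRecord",
    "central_slice",
    "fit_max_cube",
    "extract_voi",
    "qc_filter",
    "MIN_RELATIVE_RESOLUTION",
    "MIN_CONNECTIVITY",
    "MIN_VOI_EDGE",
]

#: scans with fewer voxels than this across the mean trabecular thickness
#: cannot resolve individual trabeculae
MIN_RELATIVE_RESOLUTION = 5.0
#: minimum absolute connectivity for the continuum assumption to hold
MIN_CONNECTIVITY = 50
#: smallest acceptable VOI edge (voxels)
MIN_VOI_EDGE = 16


@dataclass
class HeadMask:
    """Segmented femoral head: full head mask plus its cortical shell.

    Arrays are (z, y, x) with z proximodistal (z increasing proximally).
    The trabecular compartment is ``head & ~cortex``.
    """

    head: np.ndarray
    cortex: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.head = np.asarray(self.head) > 0
        self.cortex = np.asarray(self.cortex) > 0
        if self.head.shape != self.cortex.shape:
            raise ValueError("head and cortex masks must share a shape")
        if not self.head.any():
            raise ValueError("head mask is empty")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")

    @property
    def trabecular(self) -> np.ndarray:
        return self.head & ~self.cortex


@dataclass
class VOISpec:
    """One cubic VOI: centre voxel, edge, and physical edge length vl (mm)."""

    center: tuple[int, int, int]  # (x, y, z)
    edge: int
    vl: float
    central_slice: int


@dataclass
class QCRecord:
    """Outcome of the specimen-exclusion rules."""

    relative_resolution: float
    conn: int
    passed: bool
    reasons: list[str] = field(default_factory=list)


def central_slice(head: HeadMask) -> int:
    """Index of the plane dividing the head into distal and proximal halves.

    Returns the z index for which the head voxel counts strictly below and
    strictly above the slice are as equal as possible (the slice itself
    belongs to neither half); ties are broken toward the distal (lower z)
    side.
    """
    counts = head.head.sum(axis=(1, 2)).astype(np.int64)
    below = np.concatenate([[0], np.cumsum(counts)[:-1]])
    above = counts.sum() - below - counts
    imbalance = np.abs(below - above)
    return int(np.argmin(imbalance))  # argmin takes the first (distal) tie


def fit_max_cube(head: HeadMask, central: int | None = None) -> VOISpec:
    """Largest trabecular cube centred (in z) on the central slice.

    The cube has an odd edge so that it is symmetric about the central
    slice, contains no cortical voxel and stays inside the head; among all
    largest cubes the one whose centre is nearest (in-plane) to the
    trabecular centroid of the central slice is returned — a reproducible
    stand-in for "maximum spread over the eight corners".
    """
    if central is None:
        central = central_slice(head)
    trab = head.trabecular
    if not trab[central].any():
        raise ValueError("no trabecular bone on the central slice")
    # chessboard distance to the nearest non-trabecular voxel (grid faces
    # count as outside): d means a cube of edge 2d-1 centred there fits
    padded = np.pad(trab, 1)
    cdt = ndimage.distance_transform_cdt(padded, metric="chessboard")[1:-1, 1:-1, 1:-1]
    plane = cdt[central]
    dmax = int(plane.max())
    edge = 2 * dmax - 1
    if edge < MIN_VOI_EDGE:
        raise ValueError(
            f"VOI too small: best cube edge {max(edge, 0)} < {MIN_VOI_EDGE} voxels"
        )
    ys, xs = np.nonzero(plane == dmax)
    cys, cxs = np.nonzero(trab[central])
    centroid = np.array([cys.mean(), cxs.mean()])
    k = int(np.argmin((ys - centroid[0]) ** 2 + (xs - centroid[1]) ** 2))
    cy, cx = int(ys[k]), int(xs[k])
    return VOISpec(
        center=(cx, cy, central),
        edge=edge,
        vl=edge * head.voxel_size,
        central_slice=central,
    )


def extract_voi(vol: BinaryVolume, spec: VOISpec) -> BinaryVolume:
    """Crop the cubic VOI out of a (binary) stack."""
    cx, cy, cz = spec.center
    h = (spec.edge - 1) // 2
    sub = vol.data[cz - h : cz + h + 1, cy - h : cy + h + 1, cx - h : cx + h + 1]
    if sub.shape != (spec.edge,) * 3:
        raise ValueError("VOI extends beyond the stack")
    return vol.with_data(sub, voi_center=spec.center, voi_edge=spec.edge)


def qc_filter(summary: MorphometrySummary) -> QCRecord:
    """Apply the specimen-exclusion thresholds to one VOI summary.

    A specimen passes when the relative resolution (TbTh / voxel size) is at
    least 5 and the absolute connectivity is at least 50; every violated
    rule is reported.
    """
    reasons: list[str] = []
    if summary.relative_resolution < MIN_RELATIVE_RESOLUTION:
        reasons.append(
            f"relative resolution {summary.relative_resolution:.3g} < {MIN_RELATIVE_RESOLUTION:g}"
        )
    if summary.conn < MIN_CONNECTIVITY:
        reasons.append(f"absolute connectivity {summary.conn} < {MIN_CONNECTIVITY}")
    return QCRecord(
        relative_resolution=summary.relative_resolution,
        conn=summary.conn,
        passed=not reasons,
        reasons=reasons,
    )
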