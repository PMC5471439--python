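"""Morphometry: segmentation, soma-area measurement, and classification.

Somata of neurons and glia differ sharply in size (roughly 389 vs 88 um^2
cross-sectional area), so a single soma-area threshold separates the two
classes.  This module segments labeled cells out of 3-D image stacks,
measures each cell's maximum cross-sectional area over z-planes, locates
the valley ("break") of the bimodal area histogram, and assigns classes
by the area threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage
from skimage import measure

from .records import GLIA, NEURON, UNASSIGNED, CellRecord, with_class
from .synth import ImagingVolume, SyntheticStack

__all__ = [
    "ClassificationRule",
    "segment_stack",
    "find_bimodal_break",
    "classify_cells",
    "count_cells",
    "load_stack",
]

#: Histogram bin width (um^2) used for pooled soma-area distributions.
DEFAULT_BIN_SIZE = 18.0


@dataclass(frozen=True)
class ClassificationRule:
    """Soma-area cutoff: neurons have area strictly above ``threshold``.

    The default 200 um^2 sits inside the empty band between the glia and
    neuron area populations.  Equality is assigned to glia so the rule is
    a total partition (the boundary case is not otherwise defined by the
    morphometric criteria).
    """

    threshold: float = 200.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    def assign(self, soma_area: float) -> str:
        return NEURON if soma_area > self.threshold else GLIA


def load_stack(path: Union[str, Path],
               voxel_size: float = 1.0) -> SyntheticStack:
    """Read a multi-page TIFF (page = z-plane) as a stack with no ground
    truth attached."""
    import tifffile

    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError(f"expected a z-stack, got shape {data.shape}")
    nz, ny, nx = data.shape
    volume = ImagingVolume(
        x_extent=nx * voxel_size,
        y_extent=ny * voxel_size,
        z_extent=nz * voxel_size,
        voxel_size=voxel_size,
    )
    return SyntheticStack(
        intensities=np.asarray(data, dtype=np.uint16),
        ground_truth=[],
        volume=volume,
        seed=0,
    )


def save_stack(stack: SyntheticStack, path: Union[str, Path]) -> None:
    """Write the intensity grid as a multi-page TIFF (page = z-plane)."""
    import tifffile

    tifffile.imwrite(str(path), stack.intensities)


def segment_stack(
    stack: Union[SyntheticStack, str, Path],
    intensity_threshold: float = 0.5,
    min_voxels: int = 50,
) -> list[CellRecord]:
    """Segment bright objects out of a stack into :class:`CellRecord` s.

    Voxels above ``intensity_threshold`` x (stack maximum) are grouped
    into 26-connected 3-D components; components smaller than
    ``min_voxels`` voxels are rejected as specks (the default 50 voxels
    corresponds to a ~4.6-um-diameter sphere at 1-um voxels).  Each
    component's ``soma_area`` is its maximum single-plane cross-section:
    max over z of (in-plane pixel count x voxel_size^2), approximating a
    cell measured at its widest confocal plane.  Components whose
    centroid falls outside the volume are dropped; cells clipped by the
    border are kept as long as their centroid is inside.
    """
    if isinstance(stack, (str, Path)):
        stack = load_stack(stack)
    if not 0 < intensity_threshold < 1:
        raise ValueError("intensity_threshold must be in (0, 1)")
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    data = stack.intensities
    if data.size == 0:
        raise ValueError("empty stack")
    peak = data.max()
    if peak == 0:
        return []
    mask = data > intensity_threshold * float(peak)
    labels = measure.label(mask, connectivity=3)  # 26-connectivity in 3-D
    n_labels = labels.max()
    if n_labels == 0:
        return []
    v = stack.volume.voxel_size
    records: list[CellRecord] = []
    counts = np.bincount(labels.ravel())
    # per-component centroid in voxel coordinates (z, y, x)
    centroids = ndimage.center_of_mass(mask, labels, range(1, n_labels + 1))
    cell_id = 0
    for lab in range(1, n_labels + 1):
        if counts[lab] < min_voxels:
            continue
        zc, yc, xc = centroids[lab - 1]
        centroid = ((xc + 0.5) * v, (yc + 0.5) * v, (zc + 0.5) * v)
        if not stack.volume.contains(centroid):
            continue
        # max in-plane cross-section over z
        zs = np.nonzero((labels == lab).any(axis=(1, 2)))[0]
        per_plane = [(labels[z] == lab).sum() for z in zs]
        soma_area = float(max(per_plane)) * v * v
        records.append(
            CellRecord(
                cell_id=cell_id,
                centroid=centroid,
                soma_area=soma_area,
                voxel_count=int(counts[lab]),
                assigned_class=UNASSIGNED,
            )
        )
        cell_id += 1
    return records


def find_bimodal_break(
    areas: Sequence[float],
    bin_size: float = DEFAULT_BIN_SIZE,
) -> Optional[float]:
    """Locate the valley between the two modes of a bimodal area histogram.

    Areas are binned at ``bin_size`` um^2 with bin edges anchored at zero
    (so the binning does not depend on the sample minimum).  The two
    modes are the two highest-count local maxima of the histogram; the
    break is the midpoint of the minimum-count bin strictly between them,
    with ties resolved to the center of the tied run.  Returns ``None``
    when the histogram is not bimodal (fewer than two separated modes) —
    e.g. for unimodal or constant input.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size < 2:
        raise ValueError("need at least two areas")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    lo = np.floor(areas.min() / bin_size) * bin_size
    hi = np.ceil(areas.max() / bin_size) * bin_size
    if hi <= lo:
        hi = lo + bin_size
    edges = np.arange(lo, hi + bin_size / 2, bin_size)
    counts, edges = np.histogram(areas, bins=edges)
    if len(counts) < 3:
        return None
    # local maxima: strictly greater than one neighbor, at least equal to
    # the other (plateau ends count once via first-index convention)
    maxima = []
    for i in range(len(counts)):
        left = counts[i - 1] if i > 0 else -1
        right = counts[i + 1] if i < len(counts) - 1 else -1
        if counts[i] > 0 and counts[i] > left and counts[i] >= right:
            maxima.append(i)
    if len(maxima) < 2:
        return None
    # the two dominant modes
    maxima.sort(key=lambda i: counts[i], reverse=True)
    m1, m2 = sorted(maxima[:2])
    if m2 - m1 < 2:
        return None  # adjacent bins: no interior valley to speak of
    interior = counts[m1 + 1:m2]
    vmin = interior.min()
    if vmin >= counts[m1] or vmin >= counts[m2]:
        return None  # no real dip between the candidate modes
    # ties: several interior bins may share the minimum count (the valley
    # between well-separated modes is often a run of empty bins).  The
    # break is the center of the longest contiguous run of minimum bins
    # (first such run if tied), i.e. the middle of the valley floor.
    tied = np.nonzero(interior == vmin)[0] + m1 + 1
    runs = np.split(tied, np.nonzero(np.diff(tied) > 1)[0] + 1)
    run = max(runs, key=len)
    return float((edges[run[0]] + edges[run[-1] + 1]) / 2)


def classify_cells(
    records: Sequence[CellRecord],
    rule: ClassificationRule | None = None,
) -> list[CellRecord]:
    """Assign each record to neuron or glia by the soma-area rule.

    The partition is exhaustive and exclusive: every record comes back
    with ``assigned_class`` set to exactly one of the two classes.
    """
    rule = rule or ClassificationRule()
    out = []
    for rec in records:
        if rec.soma_area is None or rec.soma_area <= 0:
            raise ValueError(f"record {rec.cell_id} has no valid soma_area")
        out.append(with_class(rec, rule.assign(rec.soma_area)))
    return out


def count_cells(records: Sequence[CellRecord]) -> tuple[int, int]:
    """Count classified records; returns ``(neuron_count, glia_count)``."""
    neurons = glia = 0
    for rec in records:
        if rec.assigned_class == NEURON:
            neurons += 1
        elif rec.assigned_class == GLIA:
            glia += 1
        else:
            raise ValueError(f"record {rec.cell_id} is unclassified")
    return neurons, glia
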