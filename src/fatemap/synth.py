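"""Synthetic data generation: cohorts, soma-area samples, and image stacks.

The downstream analysis (morphometric classification, per-condition
counting, resampling statistics, extrapolation) assumes a particular
statistical structure in its inputs:

* two non-overlapping soma-area populations — neurons around 389 um^2 and
  glia around 88 um^2 — separable by a single area threshold;
* per-condition cell counts reported as mean +/- SD over n = 3 animals,
  for one constitutive-Cre reference condition and five tamoxifen
  timepoints (E7.5-E11.5) of the inducible line;
* confocal-style image stacks of a 350 x 350 x 100 um test volume at
  1-um isotropic voxels, in which labeled somata are resolvable objects.

This module generates data with exactly that structure, with ground truth
attached, so every pipeline stage can be validated end to end.

Soma areas are drawn from truncated normals.  Untruncated normals with the
nominal moments would overlap (about 3% of neuron draws fall below
200 um^2), so neuron areas are truncated below at ``neuron_floor`` and
glia areas above at ``glia_ceiling``.  One-sided truncation alone would
bias the achieved neuron mean upward by ~9 um^2; to keep the achieved
means on the nominal values, the pre-truncation location of each class is
re-solved numerically so that the *post-truncation* mean equals the
nominal mean.  The achieved SD is slightly below nominal (about 92 vs
102 um^2 for neurons); see docs/methods.md.

Every stochastic operation takes an explicit integer seed; there is no
global random state, and identical seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .records import (
    CONSTITUTIVE,
    GLIA,
    INDUCIBLE,
    NEURON,
    NO_TAMOXIFEN,
    TAMOXIFEN_DAYS,
    AnimalSample,
    CellRecord,
    CohortDataset,
)

__all__ = [
    "AreaModel",
    "CohortDesign",
    "ConditionSpec",
    "ImagingVolume",
    "SyntheticStack",
    "default_area_model",
    "default_cohort_design",
    "generate_soma_areas",
    "generate_cohort",
    "render_stack",
    "sample_cell_scene",
]


@dataclass(frozen=True)
class AreaModel:
    """Two-class soma-area model (um^2).

    Neuron and glia areas follow normals with the given moments, truncated
    at ``neuron_floor`` (below) and ``glia_ceiling`` (above) respectively
    so the two populations cannot overlap.  Glia areas are additionally
    bounded below at zero.
    """

    neuron_mean: float = 389.0
    neuron_sd: float = 102.0
    glia_mean: float = 88.0
    glia_sd: float = 22.0
    neuron_floor: float = 210.0
    glia_ceiling: float = 160.0

    def __post_init__(self) -> None:
        vals = (self.neuron_mean, self.neuron_sd, self.glia_mean,
                self.glia_sd, self.neuron_floor, self.glia_ceiling)
        if any(v <= 0 for v in vals):
            raise ValueError("all AreaModel fields must be positive")
        if self.glia_ceiling >= self.neuron_floor:
            raise ValueError(
                "glia_ceiling must lie below neuron_floor so the two "
                "area populations cannot overlap"
            )


@dataclass(frozen=True)
class ConditionSpec:
    """Design parameters for one (genotype, tamoxifen day) condition."""

    genotype: str
    tamoxifen_day: str
    neuron_count_mean: float
    neuron_count_sd: float
    glia_count_mean: float
    glia_count_sd: float

    def __post_init__(self) -> None:
        if self.genotype not in (CONSTITUTIVE, INDUCIBLE):
            raise ValueError(f"bad genotype {self.genotype!r}")
        if self.genotype == CONSTITUTIVE and self.tamoxifen_day != NO_TAMOXIFEN:
            raise ValueError("constitutive condition has tamoxifen_day='none'")
        if self.neuron_count_mean < 0 or self.glia_count_mean < 0:
            raise ValueError("count means must be >= 0")
        if self.neuron_count_sd < 0 or self.glia_count_sd < 0:
            raise ValueError("count SDs must be >= 0")


@dataclass(frozen=True)
class CohortDesign:
    """Full experimental design: conditions x animals per condition."""

    conditions: tuple[ConditionSpec, ...]
    n_animals_per_condition: int = 3

    def __post_init__(self) -> None:
        if self.n_animals_per_condition < 1:
            raise ValueError("need at least one animal per condition")
        if not self.conditions:
            raise ValueError("design has no conditions")


@dataclass(frozen=True)
class ImagingVolume:
    """Imaged test volume in micrometres, with isotropic voxels."""

    x_extent: float = 350.0
    y_extent: float = 350.0
    z_extent: float = 100.0
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        if min(self.x_extent, self.y_extent, self.z_extent,
               self.voxel_size) <= 0:
            raise ValueError("volume extents and voxel size must be positive")
        for ext in (self.x_extent, self.y_extent, self.z_extent):
            if abs(ext / self.voxel_size - round(ext / self.voxel_size)) > 1e-9:
                raise ValueError("extents must be divisible by voxel_size")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Grid shape as (z, y, x) voxel counts."""
        v = self.voxel_size
        return (round(self.z_extent / v), round(self.y_extent / v),
                round(self.x_extent / v))

    def contains(self, point: Sequence[float]) -> bool:
        x, y, z = point
        return (0 <= x <= self.x_extent and 0 <= y <= self.y_extent
                and 0 <= z <= self.z_extent)


@dataclass
class SyntheticStack:
    """Rendered image stack plus ground truth.

    ``intensities`` is a (z, y, x) uint16 grid; ``ground_truth`` carries one
    :class:`CellRecord` per rendered cell with its true class and analytic
    maximum cross-section area pi*a*b.
    """

    intensities: np.ndarray
    ground_truth: list[CellRecord]
    volume: ImagingVolume
    seed: int

    def __post_init__(self) -> None:
        if tuple(self.intensities.shape) != self.volume.shape:
            raise ValueError(
                f"grid shape {self.intensities.shape} does not match "
                f"volume shape {self.volume.shape}"
            )
        for cell in self.ground_truth:
            if not self.volume.contains(cell.centroid):
                raise ValueError(
                    f"ground-truth centroid {cell.centroid} outside volume"
                )


def default_area_model() -> AreaModel:
    """Soma-area model with the reference moments for both classes."""
    return AreaModel()


#: Reference per-condition counts (mean, SD over n = 3 animals) for
#: tdTomato-labeled neurons and glia in the 350 x 350 x 100 um preBotC
#: test volume: the constitutive-Cre line as the 100% reference, then
#: the inducible line at each tamoxifen timepoint.
_REFERENCE_CONDITIONS = (
    ConditionSpec(CONSTITUTIVE, NO_TAMOXIFEN, 70, 1, 92, 4),
    ConditionSpec(INDUCIBLE, "E7.5", 23, 1, 47, 7),
    ConditionSpec(INDUCIBLE, "E8.5", 38, 7, 30, 6),
    ConditionSpec(INDUCIBLE, "E9.5", 63, 4, 42, 1),
    ConditionSpec(INDUCIBLE, "E10.5", 26, 3, 38, 3),
    ConditionSpec(INDUCIBLE, "E11.5", 9, 3, 34, 3),
)


def default_cohort_design(n_animals_per_condition: int = 3) -> CohortDesign:
    """The reference experimental design: 6 conditions x n animals."""
    return CohortDesign(_REFERENCE_CONDITIONS, n_animals_per_condition)


def _truncnorm_location(target_mean: float, sd: float,
                        lower: float, upper: float) -> float:
    """Pre-truncation location whose truncated-normal mean hits the target.

    Solved by bisection on the monotone map loc -> E[X | lower <= X <= upper].
    """
    def gap(loc: float) -> float:
        a = (lower - loc) / sd
        b = (upper - loc) / sd
        return sps.truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    lo, hi = target_mean - 6 * sd, target_mean + 6 * sd
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10))


def _sample_truncated(n: int, mean: float, sd: float, lower: float,
                      upper: float, rng: np.random.Generator) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    loc = _truncnorm_location(mean, sd, lower, upper)
    a = (lower - loc) / sd
    b = (upper - loc) / sd
    return sps.truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)


def generate_soma_areas(
    n_neurons: int,
    n_glia: int,
    model: AreaModel | None = None,
    seed: int = 0,
) -> list[tuple[float, str]]:
    """Draw soma areas (um^2) for ``n_neurons`` neurons and ``n_glia`` glia.

    Returns a list of ``(area, true_class)`` pairs, neurons first.  Neuron
    areas are >= ``model.neuron_floor``; glia areas lie in
    ``(0, model.glia_ceiling]``, so the two samples never overlap.
    """
    if n_neurons < 0 or n_glia < 0:
        raise ValueError("cell counts must be non-negative")
    model = model or default_area_model()
    rng = np.random.default_rng(seed)
    neuron_areas = _sample_truncated(
        n_neurons, model.neuron_mean, model.neuron_sd,
        model.neuron_floor, np.inf, rng)
    glia_areas = _sample_truncated(
        n_glia, model.glia_mean, model.glia_sd, 0.0, model.glia_ceiling, rng)
    return (
        [(float(a), NEURON) for a in neuron_areas]
        + [(float(a), GLIA) for a in glia_areas]
    )


def generate_cohort(design: CohortDesign | None = None,
                    seed: int = 0) -> CohortDataset:
    """Simulate per-animal neuron/glia counts for a whole cohort.

    Counts are normal draws with each condition's mean/SD, rounded to the
    nearest integer and truncated below at zero (mean - 3 SD can be
    negative for the sparsest timepoints).  ``sd = 0`` gives every animal
    exactly the rounded mean.
    """
    design = design or default_cohort_design()
    rng = np.random.default_rng(seed)
    animals: list[AnimalSample] = []
    for cond in design.conditions:
        n = design.n_animals_per_condition
        neurons = rng.normal(cond.neuron_count_mean, cond.neuron_count_sd, n)
        glia = rng.normal(cond.glia_count_mean, cond.glia_count_sd, n)
        neurons = np.clip(np.rint(neurons), 0, None).astype(int)
        glia = np.clip(np.rint(glia), 0, None).astype(int)
        tag = (cond.tamoxifen_day if cond.genotype == INDUCIBLE
               else cond.genotype)
        for i in range(n):
            animals.append(
                AnimalSample(
                    animal_id=f"{tag}-{i + 1}",
                    genotype=cond.genotype,
                    tamoxifen_day=cond.tamoxifen_day,
                    neuron_count=int(neurons[i]),
                    glia_count=int(glia[i]),
                )
            )
    return CohortDataset(animals)


@dataclass(frozen=True)
class CellSpec:
    """Placement of one cell to render: centroid (um), ellipsoid radii
    (a, b, c) along (x, y, z) in um, and its class."""

    centroid: tuple[float, float, float]
    radii: tuple[float, float, float]
    cell_class: str

    @property
    def soma_area(self) -> float:
        """Analytic maximum cross-section area pi*a*b (um^2)."""
        return math.pi * self.radii[0] * self.radii[1]


def _radii_from_area(area: float, z_flattening: float = 0.75
                     ) -> tuple[float, float, float]:
    """Equatorial radii a = b with pi*a*b = area; polar radius c flattened.

    Somata are rendered as axis-aligned spheroids slightly flattened along
    z, which is typical of confocal geometry; the in-plane cross-section
    (the measured quantity) is unaffected by the flattening.
    """
    r = math.sqrt(area / math.pi)
    return (r, r, z_flattening * r)


def sample_cell_scene(
    n_neurons: int,
    n_glia: int,
    volume: ImagingVolume | None = None,
    model: AreaModel | None = None,
    seed: int = 0,
    margin: float = 2.0,
    max_tries: int = 10_000,
) -> list[CellSpec]:
    """Place non-overlapping cells uniformly at random in the volume.

    Each cell's soma area is drawn from ``model``; positions are rejected
    until the bounding spheres (plus ``margin`` um of clearance) of all
    cells are disjoint and each centroid sits far enough from the border
    for the whole soma to fit.  Raises if the volume cannot accommodate
    the requested density within ``max_tries`` proposals per cell.
    """
    volume = volume or ImagingVolume()
    areas = generate_soma_areas(n_neurons, n_glia, model, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    placed: list[CellSpec] = []
    centers: list[np.ndarray] = []
    radii_max: list[float] = []
    for area, cls in areas:
        a, b, c = _radii_from_area(area)
        rmax = max(a, b, c)
        for _ in range(max_tries):
            x = rng.uniform(a, volume.x_extent - a)
            y = rng.uniform(b, volume.y_extent - b)
            z = rng.uniform(c, volume.z_extent - c)
            p = np.array([x, y, z])
            ok = all(
                np.linalg.norm(p - q) > rmax + qr + margin
                for q, qr in zip(centers, radii_max)
            )
            if ok:
                placed.append(CellSpec((x, y, z), (a, b, c), cls))
                centers.append(p)
                radii_max.append(rmax)
                break
        else:
            raise RuntimeError(
                f"could not place cell {len(placed) + 1}/{len(areas)} "
                f"without overlap; volume too crowded"
            )
    return placed


def render_stack(
    cells: Sequence[CellSpec],
    volume: ImagingVolume | None = None,
    blur_sigma: float = 1.0,
    noise_scale: float = 0.0,
    seed: int = 0,
    amplitude: int = 1000,
) -> SyntheticStack:
    """Render cells as solid ellipsoids into a 16-bit grayscale stack.

    Each cell becomes an axis-aligned solid ellipsoid of intensity
    ``amplitude`` evaluated at voxel centers, the whole grid is Gaussian
    blurred with ``blur_sigma`` (um, 0 disables), and Poisson shot noise
    is applied when ``noise_scale > 0``: the observed voxel value is a
    Poisson draw with expectation ``noise_scale`` photons at full
    intensity, rescaled back to the amplitude range.

    The returned stack's ground truth carries each cell's analytic
    maximum-cross-section area pi*a*b and true class.
    """
    volume = volume or ImagingVolume()
    v = volume.voxel_size
    nz, ny, nx = volume.shape
    grid = np.zeros((nz, ny, nx), dtype=np.float64)
    truth: list[CellRecord] = []
    for idx, cell in enumerate(cells):
        cx, cy, cz = cell.centroid
        if not volume.contains(cell.centroid):
            raise ValueError(f"cell centroid {cell.centroid} outside volume")
        a, b, c = cell.radii
        if min(a, b, c) <= 0:
            raise ValueError("ellipsoid radii must be positive")
        # voxel-center coordinates: voxel (k, j, i) is centered at
        # ((i + .5) v, (j + .5) v, (k + .5) v) in (x, y, z)
        i0 = max(int((cx - a) / v - 1), 0)
        i1 = min(int((cx + a) / v + 2), nx)
        j0 = max(int((cy - b) / v - 1), 0)
        j1 = min(int((cy + b) / v + 2), ny)
        k0 = max(int((cz - c) / v - 1), 0)
        k1 = min(int((cz + c) / v + 2), nz)
        xs = (np.arange(i0, i1) + 0.5) * v
        ys = (np.arange(j0, j1) + 0.5) * v
        zs = (np.arange(k0, k1) + 0.5) * v
        dz2 = ((zs - cz) / c) ** 2
        dy2 = ((ys - cy) / b) ** 2
        dx2 = ((xs - cx) / a) ** 2
        mask = (dz2[:, None, None] + dy2[None, :, None]
                + dx2[None, None, :]) <= 1.0
        sub = grid[k0:k1, j0:j1, i0:i1]
        sub[mask] = amplitude
        truth.append(
            CellRecord(
                cell_id=idx,
                centroid=cell.centroid,
                soma_area=cell.soma_area,
                voxel_count=int(mask.sum()),
                assigned_class="unassigned",
                true_class=cell.cell_class,
            )
        )
    if blur_sigma > 0:
        from scipy import ndimage

        grid = ndimage.gaussian_filter(grid, sigma=blur_sigma / v)
    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        lam = grid / amplitude * noise_scale
        grid = rng.poisson(lam).astype(np.float64) * (amplitude / noise_scale)
    intensities = np.clip(np.rint(grid), 0, np.iinfo(np.uint16).max)
    return SyntheticStack(
        intensities=intensities.astype(np.uint16),
        ground_truth=truth,
        volume=volume,
        seed=seed,
    )
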