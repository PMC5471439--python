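"""Core data containers shared across the pipeline.

A :class:`CellRecord` is one segmented (or simulated) cell; an
:class:`AnimalSample` is one animal's neuron/glia count pair under a single
experimental condition; a :class:`CohortDataset` is the full design —
six conditions (one constitutive-Cre reference plus five tamoxifen
timepoints of the inducible line) with a small number of animals each.

All containers round-trip through plain CSV so that every pipeline stage
can be driven from files as well as from Python objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

NEURON = "neuron"
GLIA = "glia"
UNASSIGNED = "unassigned"

CONSTITUTIVE = "constitutive"
INDUCIBLE = "inducible"

#: Tamoxifen-administration label used for the constitutive-Cre reference,
#: which involves no tamoxifen at all.
NO_TAMOXIFEN = "none"

#: Embryonic days at which tamoxifen was administered to pregnant dams.
TAMOXIFEN_DAYS = ("E7.5", "E8.5", "E9.5", "E10.5", "E11.5")

CELL_CSV_COLUMNS = [
    "cell_id", "x", "y", "z", "soma_area_um2", "voxel_count",
    "assigned_class", "true_class",
]

COHORT_CSV_COLUMNS = [
    "animal_id", "genotype", "tamoxifen_day", "neuron_count", "glia_count",
]


@dataclass
class CellRecord:
    """One cell: centroid in micrometres, soma area, and class labels.

    ``soma_area`` is the maximum cross-sectional area of the cell body over
    z-planes, the morphometric feature that separates neurons (large somata)
    from glia (small somata).  ``true_class`` is only available for
    synthetic cells where ground truth is known.
    """

    cell_id: int
    centroid: tuple[float, float, float]  # (x, y, z) in um
    soma_area: float  # um^2
    voxel_count: int = 0
    assigned_class: str = UNASSIGNED
    true_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.soma_area <= 0:
            raise ValueError(f"soma_area must be positive, got {self.soma_area}")
        if self.assigned_class not in (NEURON, GLIA, UNASSIGNED):
            raise ValueError(f"bad assigned_class {self.assigned_class!r}")
        if self.true_class not in (None, NEURON, GLIA):
            raise ValueError(f"bad true_class {self.true_class!r}")


def cells_to_frame(cells: Iterable[CellRecord]) -> pd.DataFrame:
    rows = [
        {
            "cell_id": c.cell_id,
            "x": c.centroid[0],
            "y": c.centroid[1],
            "z": c.centroid[2],
            "soma_area_um2": c.soma_area,
            "voxel_count": c.voxel_count,
            "assigned_class": c.assigned_class,
            "true_class": c.true_class if c.true_class is not None else "",
        }
        for c in cells
    ]
    return pd.DataFrame(rows, columns=CELL_CSV_COLUMNS)


def cells_from_frame(frame: pd.DataFrame) -> list[CellRecord]:
    out = []
    for row in frame.itertuples(index=False):
        true_class = getattr(row, "true_class", "")
        if pd.isna(true_class) or true_class == "":
            true_class = None
        out.append(
            CellRecord(
                cell_id=int(row.cell_id),
                centroid=(float(row.x), float(row.y), float(row.z)),
                soma_area=float(row.soma_area_um2),
                voxel_count=int(getattr(row, "voxel_count", 0)),
                assigned_class=str(row.assigned_class),
                true_class=true_class,
            )
        )
    return out


@dataclass(frozen=True)
class AnimalSample:
    """Counts for one animal: genotype, tamoxifen day, neurons and glia."""

    animal_id: str
    genotype: str
    tamoxifen_day: str
    neuron_count: int
    glia_count: int

    def __post_init__(self) -> None:
        if self.genotype not in (CONSTITUTIVE, INDUCIBLE):
            raise ValueError(f"bad genotype {self.genotype!r}")
        if self.genotype == CONSTITUTIVE and self.tamoxifen_day != NO_TAMOXIFEN:
            raise ValueError("constitutive animals take no tamoxifen")
        if self.neuron_count < 0 or self.glia_count < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class CohortDataset:
    """All animals in the experiment, grouped by (genotype, tamoxifen_day)."""

    animals: list[AnimalSample] = field(default_factory=list)

    def __iter__(self) -> Iterator[AnimalSample]:
        return iter(self.animals)

    def __len__(self) -> int:
        return len(self.animals)

    def conditions(self) -> list[tuple[str, str]]:
        """Distinct (genotype, tamoxifen_day) pairs in input order."""
        seen: dict[tuple[str, str], None] = {}
        for a in self.animals:
            seen.setdefault((a.genotype, a.tamoxifen_day), None)
        return list(seen)

    def counts_for(self, genotype: str, tamoxifen_day: str,
                   cell_class: str) -> list[int]:
        attr = "neuron_count" if cell_class == NEURON else "glia_count"
        return [
            getattr(a, attr)
            for a in self.animals
            if a.genotype == genotype and a.tamoxifen_day == tamoxifen_day
        ]

    def counts_by_day(self, cell_class: str = NEURON) -> dict[str, list[int]]:
        """Per-timepoint count lists for the inducible line only."""
        out: dict[str, list[int]] = {}
        for a in self.animals:
            if a.genotype != INDUCIBLE:
                continue
            out.setdefault(a.tamoxifen_day, []).append(
                a.neuron_count if cell_class == NEURON else a.glia_count
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "animal_id": a.animal_id,
                "genotype": a.genotype,
                "tamoxifen_day": a.tamoxifen_day,
                "neuron_count": a.neuron_count,
                "glia_count": a.glia_count,
            }
            for a in self.animals
        ]
        return pd.DataFrame(rows, columns=COHORT_CSV_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CohortDataset":
        animals = [
            AnimalSample(
                animal_id=str(row.animal_id),
                genotype=str(row.genotype),
                tamoxifen_day=str(row.tamoxifen_day),
                neuron_count=int(row.neuron_count),
                glia_count=int(row.glia_count),
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(animals)

    @classmethod
    def from_csv(cls, path) -> "CohortDataset":
        return cls.from_frame(pd.read_csv(path))


def with_class(record: CellRecord, assigned_class: str) -> CellRecord:
    """Copy of ``record`` with ``assigned_class`` set."""
    return replace(record, assigned_class=assigned_class)
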