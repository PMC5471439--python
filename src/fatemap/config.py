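"""Run configuration: a single YAML/JSON document driving the pipeline.

A config nests all stage parameters (area model, cohort design, imaging
volume, classification rule, resampling settings, extrapolation
geometry) plus a seed and output directory.  The ``reference_defaults``
preset embeds the reference per-condition means/SDs so a full run needs
nothing beyond a seed and an output path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Union

import yaml

from .extrap import ExtrapolationSpec
from .morpho import ClassificationRule
from .synth import (
    AreaModel,
    CohortDesign,
    ConditionSpec,
    ImagingVolume,
    default_cohort_design,
)

__all__ = ["RunConfig", "ResamplingSettings", "load_config", "reference_defaults"]


@dataclass(frozen=True)
class ResamplingSettings:
    n_resamples: int = 10_000
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class RunConfig:
    seed: int = 0
    area_model: AreaModel = field(default_factory=AreaModel)
    cohort_design: CohortDesign = field(default_factory=default_cohort_design)
    imaging_volume: ImagingVolume = field(default_factory=ImagingVolume)
    classification_rule: ClassificationRule = field(
        default_factory=ClassificationRule)
    resampling: ResamplingSettings = field(default_factory=ResamplingSettings)
    extrapolation: ExtrapolationSpec = field(default_factory=ExtrapolationSpec)
    output_dir: Path = Path("fatemap-run")

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)


def reference_defaults(seed: int = 0,
                       output_dir: Union[str, Path] = "fatemap-run"
                       ) -> RunConfig:
    """Config preset with the reference design and all default parameters."""
    return RunConfig(seed=seed, output_dir=Path(output_dir))


def _build_design(raw: Mapping[str, Any]) -> CohortDesign:
    conditions = tuple(
        ConditionSpec(
            genotype=c["genotype"],
            tamoxifen_day=str(c["tamoxifen_day"]),
            neuron_count_mean=float(c["neuron_count_mean"]),
            neuron_count_sd=float(c["neuron_count_sd"]),
            glia_count_mean=float(c["glia_count_mean"]),
            glia_count_sd=float(c["glia_count_sd"]),
        )
        for c in raw["conditions"]
    )
    return CohortDesign(conditions, int(raw.get("n_animals_per_condition", 3)))


def _from_mapping(doc: Mapping[str, Any]) -> RunConfig:
    cfg = reference_defaults()
    kwargs: dict[str, Any] = {
        "seed": int(doc.get("seed", 0)),
        "output_dir": Path(doc.get("output_dir", "fatemap-run")),
    }
    if "area_model" in doc:
        kwargs["area_model"] = AreaModel(**doc["area_model"])
    if "cohort_design" in doc:
        raw = doc["cohort_design"]
        kwargs["cohort_design"] = (
            default_cohort_design(int(raw.get("n_animals_per_condition", 3)))
            if raw.get("preset") == "reference" else _build_design(raw)
        )
    if "imaging_volume" in doc:
        kwargs["imaging_volume"] = ImagingVolume(**doc["imaging_volume"])
    if "classification_rule" in doc:
        kwargs["classification_rule"] = ClassificationRule(
            **doc["classification_rule"])
    if "resampling" in doc:
        kwargs["resampling"] = ResamplingSettings(**doc["resampling"])
    if "extrapolation" in doc:
        kwargs["extrapolation"] = ExtrapolationSpec(**doc["extrapolation"])
    return RunConfig(**kwargs)


def load_config(path: Union[str, Path]) -> RunConfig:
    """Read a YAML or JSON run configuration.

    Unknown keys inside a section raise (typo protection); a missing
    section falls back to its default.  ``cohort_design: {preset:
    reference}`` selects the embedded reference design.
    """
    path = Path(path)
    text = path.read_text()
    doc = (json.loads(text) if path.suffix.lower() == ".json"
           else yaml.safe_load(text))
    if not isinstance(doc, Mapping):
        raise ValueError(f"config {path} is not a mapping")
    return _from_mapping(doc)
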