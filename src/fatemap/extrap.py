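"""Stereological extrapolation of total cell number.

Counts are taken in a 350 x 350 um unilateral test window sampled over a
100-um depth at the core of the structure; the structure itself spans
~440 um rostrocaudally and is bilateral.  Assuming uniform density along
the rostrocaudal axis, the total is the sampled mean scaled by the depth
ratio and the bilateral factor; the transverse window matches the
structure's transverse extent and therefore cancels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["ExtrapolationSpec", "ExtrapolationResult", "extrapolate_total",
           "labeling_sum_check"]


@dataclass(frozen=True)
class ExtrapolationSpec:
    """Geometry for scaling a sampled count to the whole structure.

    ``bilateral_factor`` defaults to 2 because imaging is unilateral
    while the structure is bilateral; set 1 for a unilateral estimate.
    The 350 x 350 um transverse window is informational only — it equals
    the structure's transverse extent, so it cancels in the ratio.
    """

    sampled_depth: float = 100.0  # um
    rostrocaudal_extent: float = 440.0  # um
    bilateral_factor: int = 2

    def __post_init__(self) -> None:
        if self.sampled_depth <= 0 or self.rostrocaudal_extent <= 0:
            raise ValueError("extents must be positive")
        if self.bilateral_factor not in (1, 2):
            raise ValueError("bilateral_factor must be 1 or 2")


@dataclass(frozen=True)
class ExtrapolationResult:
    mean_count_per_volume: float
    spec: ExtrapolationSpec
    estimate: float  # unrounded

    @property
    def display(self) -> int:
        """Rounded headline value (~554 for the reference neuron mean)."""
        return round(self.estimate)


def extrapolate_total(mean_count_per_volume: float,
                      spec: ExtrapolationSpec | None = None
                      ) -> ExtrapolationResult:
    """Scale a mean per-test-volume count to a whole-structure estimate.

    estimate = mean x (rostrocaudal_extent / sampled_depth)
                    x bilateral_factor

    Linear in both the count and the rostrocaudal extent; with
    ``sampled_depth == rostrocaudal_extent`` and ``bilateral_factor == 1``
    the estimate equals the input.
    """
    if mean_count_per_volume < 0:
        raise ValueError("mean count must be >= 0")
    spec = spec or ExtrapolationSpec()
    estimate = (mean_count_per_volume
                * (spec.rostrocaudal_extent / spec.sampled_depth)
                * spec.bilateral_factor)
    return ExtrapolationResult(mean_count_per_volume, spec, float(estimate))


def labeling_sum_check(per_day_means: Sequence[float],
                       constitutive_mean: float) -> float:
    """Summed labeling across timepoints as a percentage of the
    constitutive reference.

    Values above 100% indicate that inducible labeling windows overlap:
    recombinase activity persists beyond a single day, so successive
    tamoxifen timepoints label overlapping progenitor populations.
    """
    if constitutive_mean <= 0:
        raise ValueError("constitutive mean must be positive")
    return 100.0 * float(sum(per_day_means)) / constitutive_mean
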