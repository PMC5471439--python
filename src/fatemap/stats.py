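"""Cohort summaries and resampling statistics.

The central inferential question: does the number of labeled neurons
depend on *when* tamoxifen was administered?  With n = 3 animals per
timepoint, parametric ANOVA is fragile, so significance is assessed by a
shuffle-and-resample procedure: pool all per-animal counts across the
five timepoints, repeatedly permute the pooled values and deal them back
into groups of three (sampling without replacement within each shuffle),
and record each timepoint's resampled mean.  The middle 99% of each
timepoint's resampled means forms its confidence band; an observed mean
falling outside its band is significant at alpha = 0.01.

An exact-enumeration oracle (:func:`exact_permutation_oracle`) computes
the same null distribution by brute force on small inputs, for
validating the Monte-Carlo machinery.

Empirical two-sided P values are doubled one-sided tail probabilities of
the day's own resampled-mean distribution, with the add-one correction
so P is never zero:

    P = min(1, 2 * min(P_lo, P_hi)),
    P_hi = (1 + #{resampled >= observed}) / (1 + n_resamples)

and symmetrically for ``P_lo``.  This definition is consistent with the
confidence-band rule: P < alpha corresponds (up to Monte-Carlo ties) to
the observed mean lying outside the equal-tailed 1 - alpha band.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .records import GLIA, NEURON, CohortDataset, CONSTITUTIVE, INDUCIBLE, NO_TAMOXIFEN

__all__ = [
    "ConditionSummary",
    "ResamplingResult",
    "summarize_cohort",
    "percent_of_constitutive",
    "resampling_test",
    "exact_permutation_oracle",
    "soma_area_comparison",
]


@dataclass
class ConditionSummary:
    """Mean +/- SD of one cell class in one condition, with the labeling
    percentage relative to the constitutive-Cre reference."""

    genotype: str
    tamoxifen_day: str
    cell_class: str
    per_animal_counts: list[int]
    mean: float
    sd: float
    pct_of_constitutive: Optional[float] = None


def summarize_cohort(cohort: CohortDataset) -> list[ConditionSummary]:
    """One summary per (condition, cell class).

    ``sd`` is the sample standard deviation (ddof = 1; 0 for a single
    animal).  When the cohort contains a constitutive condition,
    ``pct_of_constitutive`` is filled for every summary of the same cell
    class, with the constitutive condition itself at 100%.
    """
    summaries: list[ConditionSummary] = []
    for genotype, day in cohort.conditions():
        for cls in (NEURON, GLIA):
            counts = cohort.counts_for(genotype, day, cls)
            if not counts:
                raise ValueError(f"condition ({genotype}, {day}) has no animals")
            arr = np.asarray(counts, dtype=float)
            sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
            summaries.append(
                ConditionSummary(
                    genotype=genotype,
                    tamoxifen_day=day,
                    cell_class=cls,
                    per_animal_counts=list(counts),
                    mean=float(arr.mean()),
                    sd=sd,
                )
            )
    reference = {
        s.cell_class: s.mean
        for s in summaries
        if s.genotype == CONSTITUTIVE
    }
    for s in summaries:
        ref = reference.get(s.cell_class)
        if ref is not None and ref > 0:
            s.pct_of_constitutive = percent_of_constitutive(s.mean, ref)
    return summaries


def percent_of_constitutive(condition_mean: float,
                            constitutive_mean: float) -> float:
    """Labeling of a condition as an (unrounded) percentage of the
    constitutive-Cre reference; display typically rounds to integer
    percent."""
    if constitutive_mean <= 0:
        raise ValueError("constitutive mean must be positive")
    return 100.0 * condition_mean / constitutive_mean


@dataclass
class ResamplingResult:
    """Shuffle-and-resample test output, keyed by tamoxifen day."""

    per_day_observed_mean: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    significant_high: dict[str, bool]
    significant_low: dict[str, bool]
    empirical_p: dict[str, float]
    n_resamples: int = 10_000
    alpha: float = 0.01
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "per_day_observed_mean": self.per_day_observed_mean,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "significant_high": self.significant_high,
            "significant_low": self.significant_low,
            "empirical_p": self.empirical_p,
            "n_resamples": self.n_resamples,
            "alpha": self.alpha,
            "seed": self.seed,
        }


def _resampled_means(pooled: np.ndarray, n_days: int, group_size: int,
                     n_resamples: int, rng: np.random.Generator,
                     check_conservation: bool = False) -> np.ndarray:
    """(n_resamples, n_days) matrix of group means under full shuffling."""
    mat = np.tile(pooled, (n_resamples, 1))
    mat = rng.permuted(mat, axis=1)
    if check_conservation:
        target = np.sort(pooled)
        assert np.array_equal(np.sort(mat, axis=1),
                              np.tile(target, (n_resamples, 1)))
    return mat.reshape(n_resamples, n_days, group_size).mean(axis=2)


def resampling_test(
    counts_by_day: Mapping[str, Sequence[int]],
    n_resamples: int = 10_000,
    alpha: float = 0.01,
    seed: int = 0,
    _check_conservation: bool = False,
) -> ResamplingResult:
    """Shuffle-and-resample significance test over tamoxifen timepoints.

    All counts are pooled; each of ``n_resamples`` iterations applies a
    fresh uniform permutation of the pooled values and deals them back
    into the day groups (preserving group sizes), recording each day's
    resampled mean.  Confidence bounds are the equal-tailed
    (alpha/2, 1 - alpha/2) empirical quantiles (linear interpolation) of
    that day's resampled means; a day is ``significant_high`` when its
    observed mean strictly exceeds the upper bound, ``significant_low``
    when strictly below the lower bound.

    The design must be balanced (equal group sizes), matching the
    experiment's three animals per timepoint.
    """
    days = list(counts_by_day)
    if len(days) < 2:
        raise ValueError("need at least two timepoints")
    groups = [np.asarray(counts_by_day[d], dtype=float) for d in days]
    sizes = {len(g) for g in groups}
    if len(sizes) != 1:
        raise ValueError("groups must have equal sizes (balanced design)")
    group_size = sizes.pop()
    if group_size < 1:
        raise ValueError("empty groups")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    pooled = np.concatenate(groups)
    observed = np.array([g.mean() for g in groups])
    rng = np.random.default_rng(seed)
    rm = _resampled_means(pooled, len(days), group_size, n_resamples, rng,
                          check_conservation=_check_conservation)
    lo = np.quantile(rm, alpha / 2, axis=0)
    hi = np.quantile(rm, 1 - alpha / 2, axis=0)
    p_hi = (1 + (rm >= observed[None, :]).sum(axis=0)) / (1 + n_resamples)
    p_lo = (1 + (rm <= observed[None, :]).sum(axis=0)) / (1 + n_resamples)
    p = np.minimum(1.0, 2.0 * np.minimum(p_hi, p_lo))
    return ResamplingResult(
        per_day_observed_mean={d: float(m) for d, m in zip(days, observed)},
        ci_lower={d: float(v) for d, v in zip(days, lo)},
        ci_upper={d: float(v) for d, v in zip(days, hi)},
        significant_high={d: bool(o > h) for d, o, h in zip(days, observed, hi)},
        significant_low={d: bool(o < l) for d, o, l in zip(days, observed, lo)},
        empirical_p={d: float(v) for d, v in zip(days, p)},
        n_resamples=n_resamples,
        alpha=alpha,
        seed=seed,
    )


#: Refuse exhaustive enumeration beyond this many pooled values.
ORACLE_MAX_VALUES = 12


def exact_permutation_oracle(
    counts_by_day: Mapping[str, Sequence[float]],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Exact null distribution of per-day group means by full enumeration.

    Enumerates every distinct assignment of the pooled values into the
    given group structure (groups are unordered internally, so the
    enumeration walks index combinations, which weights duplicate values
    correctly).  Returns, per day, ``(means, probabilities)`` with means
    sorted ascending.  Only feasible for small inputs; refuses more than
    ``ORACLE_MAX_VALUES`` pooled values.
    """
    days = list(counts_by_day)
    groups = [list(counts_by_day[d]) for d in days]
    sizes = [len(g) for g in groups]
    pooled = [float(v) for g in groups for v in g]
    n = len(pooled)
    if n > ORACLE_MAX_VALUES:
        raise ValueError(
            f"{n} pooled values exceed the enumeration guard "
            f"({ORACLE_MAX_VALUES}); use resampling_test instead"
        )

    pooled_arr = np.asarray(pooled)
    # accumulate, per day, mean -> number of assignments achieving it
    tallies: list[dict[float, int]] = [dict() for _ in days]
    total = 0

    def recurse(remaining: frozenset, gi: int, means: list[float]) -> None:
        nonlocal total
        if gi == len(sizes):
            total += 1
            for di, m in enumerate(means):
                tallies[di][m] = tallies[di].get(m, 0) + 1
            return
        for combo in itertools.combinations(sorted(remaining), sizes[gi]):
            m = round(float(pooled_arr[list(combo)].mean()), 12)
            recurse(remaining - frozenset(combo), gi + 1, means + [m])

    recurse(frozenset(range(n)), 0, [])
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for d, tally in zip(days, tallies):
        means = np.array(sorted(tally))
        probs = np.array([tally[m] for m in means], dtype=float) / total
        out[d] = (means, probs)
    return out


def soma_area_comparison(
    neuron_areas: Sequence[float],
    glia_areas: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Unpaired two-sample t test on soma areas.

    Welch's unequal-variance form by default; set ``equal_var=True`` for
    the pooled-variance (Student) form.  The degenerate case of zero
    variance in both groups with equal means returns ``(0.0, 1.0)`` by
    convention.
    """
    a = np.asarray(neuron_areas, dtype=float)
    b = np.asarray(glia_areas, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two areas per group")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
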