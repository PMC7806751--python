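"""Ordinal-to-count conversion and density / prevalence estimation.

The survey records only an ordinal visible-count class per morphospecies
per plate.  Estimation proceeds by (1) replacing each class with a fixed
representative count per 25 cm² plate (the standard map is
0 -> 0, + -> 10, ++ -> 50, +++ -> 100), (2) averaging mapped counts per
unit area within each host over the samples admitted by an inclusion
rule, and (3) averaging those per-host densities without weights across
hosts, so hosts with different numbers of plates contribute equally
(a two-stage, host-as-unit estimator).

Community composition is the per-species share of the summed mean
densities; prevalence is presence/absence of each species per host over
all its samples; the depth-yield ratio compares the cumulative mapped
count over all sequential passes of a skin patch with the first
(superficial) pass alone.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Mapping, Sequence

import pandas as pd

from .records import AbundanceCategory, ScrapeSample, species_order

__all__ = [
    "CategoryMapping",
    "PUBLISHED_MAPPING",
    "DensityEstimate",
    "PrevalenceSummary",
    "DepthYield",
    "EstimationError",
    "InclusionRule",
    "category_to_count",
    "host_mean_density",
    "population_mean_density",
    "composition_fractions",
    "prevalence_summary",
    "depth_yield",
]


class EstimationError(ValueError):
    """Raised when an estimate is undefined for the given inputs."""


@dataclass(frozen=True)
class CategoryMapping:
    """Representative count per ordinal level, per 25 cm² plate.

    ``counts[level]`` replaces a plate scored at that level.  Level 0 must
    map to 0 and the counts must increase strictly with level, so that
    raising a category can never lower an estimate.
    """

    counts: tuple[float, float, float, float] = (0.0, 10.0, 50.0, 100.0)

    def __post_init__(self) -> None:
        if len(self.counts) != 4:
            raise ValueError("mapping needs one count per level 0..3")
        if self.counts[0] != 0:
            raise ValueError("level 0 must map to a count of 0")
        if not all(a < b for a, b in zip(self.counts, self.counts[1:])):
            raise ValueError(f"counts must be strictly increasing: {self.counts}")

    def __getitem__(self, level: int) -> float:
        return self.counts[level]

    def scaled(self, factor: float) -> "CategoryMapping":
        return CategoryMapping(tuple(c * factor for c in self.counts))


#: The mapping used for the published survey estimates.
PUBLISHED_MAPPING = CategoryMapping((0.0, 10.0, 50.0, 100.0))


def category_to_count(
    category: AbundanceCategory, mapping: CategoryMapping = PUBLISHED_MAPPING
) -> float:
    """Representative nematode count for one plate's ordinal class."""
    return mapping[category.level]


# ---------------------------------------------------------------------------
# Inclusion rules
# ---------------------------------------------------------------------------

InclusionRule = Literal["non_sequential", "first_pass_only", "all_passes"]

_RULES: dict[str, Callable[[ScrapeSample], bool]] = {
    # drop only repeat passes over an already-scraped area; pseudoreplicate
    # plates and first passes stay in (the rule behind the published means)
    "non_sequential": lambda s: not s.is_sequential_resample,
    "first_pass_only": lambda s: s.pass_index == 1,
    "all_passes": lambda s: True,
}


def _predicate(
    rule: InclusionRule, exclude_hosts: Sequence[str] = ()
) -> Callable[[ScrapeSample], bool]:
    try:
        base = _RULES[rule]
    except KeyError:
        raise ValueError(
            f"unknown inclusion rule {rule!r}; choose from {sorted(_RULES)}"
        ) from None
    excluded = set(exclude_hosts)
    return lambda s: s.host_id not in excluded and base(s)


# ---------------------------------------------------------------------------
# Density estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DensityEstimate:
    """Per-species population mean density with its provenance.

    ``densities`` is nematodes per cm²; ``per_host`` holds the stage-one
    host means (hosts x species) that were averaged without weights.
    """

    densities: pd.Series
    per_host: pd.DataFrame
    n_hosts: int
    n_samples: int
    inclusion_rule: str
    exclude_hosts: tuple[str, ...] = ()

    @property
    def total_density(self) -> float:
        """Summed mean density over all morphospecies (nematodes/cm²)."""
        return float(self.densities.sum())

    @property
    def composition(self) -> pd.Series:
        return composition_fractions(self)


def host_mean_density(
    samples: Iterable[ScrapeSample],
    mapping: CategoryMapping = PUBLISHED_MAPPING,
    rule: InclusionRule = "non_sequential",
) -> pd.Series:
    """Mean density (nematodes/cm²) per species for one host.

    Each included plate contributes its mapped count divided by its
    scraped area; plates are averaged with equal weight.  Raises
    :class:`EstimationError` if the rule leaves no samples.
    """
    keep = _predicate(rule)
    included = [s for s in samples if keep(s)]
    if not included:
        raise EstimationError("no included samples after applying inclusion rule")
    hosts = {s.host_id for s in included}
    if len(hosts) > 1:
        raise ValueError(f"samples span multiple hosts: {sorted(hosts)}")
    order = species_order(included)
    sums = {sp: 0.0 for sp in order}
    for s in included:
        for sp in order:
            cat = s.abundances.get(sp, AbundanceCategory(0))
            sums[sp] += category_to_count(cat, mapping) / s.area_cm2
    n = len(included)
    return pd.Series({sp: sums[sp] / n for sp in order}, name=included[0].host_id)


def population_mean_density(
    samples: Iterable[ScrapeSample],
    mapping: CategoryMapping = PUBLISHED_MAPPING,
    rule: InclusionRule = "non_sequential",
    exclude_hosts: Sequence[str] = (),
) -> DensityEstimate:
    """Two-stage population mean density across hosts.

    Stage one computes each host's mean density over its included plates;
    stage two averages the host means without weights, so a host scraped
    nine times counts the same as a host scraped four times.
    """
    samples = list(samples)
    keep = _predicate(rule, exclude_hosts)
    included = [s for s in samples if keep(s)]
    if not included:
        raise EstimationError("no hosts with included samples")
    order = species_order(included)
    by_host: dict[str, list[ScrapeSample]] = {}
    for s in included:
        by_host.setdefault(s.host_id, []).append(s)
    host_rows = {
        host: host_mean_density(group, mapping, rule="all_passes")
        for host, group in by_host.items()
    }
    per_host = pd.DataFrame(host_rows).T.reindex(columns=order).fillna(0.0)
    return DensityEstimate(
        densities=per_host.mean(axis=0),
        per_host=per_host,
        n_hosts=len(per_host),
        n_samples=len(included),
        inclusion_rule=rule,
        exclude_hosts=tuple(exclude_hosts),
    )


def composition_fractions(estimate: DensityEstimate | pd.Series) -> pd.Series:
    """Per-species share of the total mean density (fractions sum to 1)."""
    densities = (
        estimate.densities if isinstance(estimate, DensityEstimate) else estimate
    )
    total = float(densities.sum())
    if total <= 0:
        raise EstimationError(
            "composition is undefined: all species densities are zero"
        )
    return densities / total


# ---------------------------------------------------------------------------
# Prevalence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrevalenceSummary:
    """Presence/absence of each species per host, over all samples."""

    presence: pd.DataFrame  # hosts x species, bool
    positive_sample_counts: pd.DataFrame  # hosts x species, int
    samples_per_host: pd.Series

    @property
    def n_hosts(self) -> int:
        return len(self.presence)

    @property
    def n_hosts_all_species(self) -> int:
        """Hosts on which every surveyed morphospecies was detected."""
        if self.presence.empty:
            return 0
        return int(self.presence.all(axis=1).sum())


def prevalence_summary(samples: Iterable[ScrapeSample]) -> PrevalenceSummary:
    """Detection summary: a species is present on a host iff any of the
    host's samples (any pass) scored it above level 0."""
    samples = list(samples)
    order = species_order(samples)
    hosts: list[str] = []
    for s in samples:
        if s.host_id not in hosts:
            hosts.append(s.host_id)
    pos = pd.DataFrame(0, index=hosts, columns=order, dtype=int)
    n_samp = pd.Series(0, index=hosts, dtype=int)
    for s in samples:
        n_samp[s.host_id] += 1
        for sp, cat in s.abundances.items():
            if cat.level >= 1:
                pos.loc[s.host_id, sp] += 1
    return PrevalenceSummary(
        presence=pos > 0, positive_sample_counts=pos, samples_per_host=n_samp
    )


# ---------------------------------------------------------------------------
# Depth-resampling yield
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DepthYield:
    """Cumulative-over-first-pass yield ratios from sequential sampling.

    ``per_host[h]`` = (summed mapped count over every pass of the host's
    sequentially sampled areas) / (mapped count of the first pass alone),
    with all species pooled within a pass.  Hosts whose first pass mapped
    to zero have an undefined ratio and are listed separately.
    """

    per_host: dict[str, float]
    undefined_hosts: tuple[str, ...]

    @property
    def min(self) -> float:
        return min(self.per_host.values())

    @property
    def max(self) -> float:
        return max(self.per_host.values())

    @property
    def median(self) -> float:
        return statistics.median(self.per_host.values())


def depth_yield(
    samples: Iterable[ScrapeSample], mapping: CategoryMapping = PUBLISHED_MAPPING
) -> DepthYield:
    """Per-host depth-resampling yield ratios.

    A sequential series is a group of plates sharing one sample-area base
    label (``A``, ``A-1``, ``A-2`` ... or ``A-1``/``A-2``) with at least
    two distinct passes.  Pseudoreplicate plates from other skin areas do
    not enter the ratio.  Raises :class:`EstimationError` when no host was
    sequentially sampled.
    """
    samples = list(samples)
    by_host: dict[str, dict[str, list[ScrapeSample]]] = {}
    for s in samples:
        by_host.setdefault(s.host_id, {}).setdefault(s.base_label, []).append(s)

    def plate_total(s: ScrapeSample) -> float:
        return sum(category_to_count(c, mapping) for c in s.abundances.values())

    ratios: dict[str, float] = {}
    undefined: list[str] = []
    for host, areas in by_host.items():
        series = [
            plates
            for plates in areas.values()
            if len({p.pass_index for p in plates}) >= 2
        ]
        if not series:
            continue
        total = sum(plate_total(p) for plates in series for p in plates)
        first = sum(
            plate_total(p)
            for plates in series
            for p in plates
            if p.pass_index == min(q.pass_index for q in plates)
        )
        if first == 0:
            undefined.append(host)
        else:
            ratios[host] = total / first
    if not ratios and not undefined:
        raise EstimationError("no sequentially sampled hosts in survey")
    return DepthYield(per_host=ratios, undefined_hosts=tuple(undefined))
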