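"""Whole-animal census: loads, extrapolation ranges and the report.

:class:`CensusModel` is the top-level modelling object: it is built from
a scrape-sample survey plus per-sex dorsal surface areas, and
:meth:`CensusModel.fit` returns a :class:`CensusResults` carrying the
per-species density estimates, community composition, prevalence,
baseline epibiont loads (density x area, per sex) and the
multiplier-adjusted load ranges, together with a text ``summary()`` and
a JSON-serialisable dict.

Baseline loads are kept unrounded internally; report-time integers use
half-up rounding, and the extrapolation ranges round the baseline to a
configurable quantum (default 10,000 nematodes) before applying the
depth multipliers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import records
from .abundance import (
    CategoryMapping,
    DensityEstimate,
    DepthYield,
    EstimationError,
    PrevalenceSummary,
    composition_fractions,
    depth_yield,
    population_mean_density,
    prevalence_summary,
)
from .config import RunConfig
from .geometry import SurfaceAreas, cohort_areas
from .records import HostMorphometrics, ScrapeSample

__all__ = [
    "CensusModel",
    "CensusResults",
    "total_load",
    "load_range",
    "round_half_up",
    "areas_from_summary",
]


def round_half_up(x: float, quantum: float = 1.0) -> float:
    """Round to the nearest multiple of ``quantum``, ties away from zero
    (commercial rounding, not banker's)."""
    if quantum <= 0:
        raise ValueError("quantum must be positive")
    return math.floor(x / quantum + 0.5) * quantum


def total_load(density_total: float, area_cm2: float) -> float:
    """Epibiont load (nematodes) on an area: summed density x area.

    The unrounded product is returned; report layers round half-up to a
    whole count.
    """
    if density_total < 0 or area_cm2 < 0:
        raise ValueError("density and area must be non-negative")
    return density_total * area_cm2


def load_range(
    baseline: float,
    multipliers: tuple[float, float],
    rounding_quantum: float = 10_000,
) -> tuple[float, float]:
    """Depth-extrapolated load range.

    The baseline load is first rounded to the nearest ``rounding_quantum``
    (the headline figures quote loads to the nearest 10,000), then
    multiplied by each endpoint of the deeper-sampling multiplier range.
    """
    m_lo, m_hi = multipliers
    if not (1 <= m_lo <= m_hi):
        raise ValueError(f"need 1 <= m_lo <= m_hi, got {multipliers}")
    base = round_half_up(baseline, rounding_quantum)
    return base * m_lo, base * m_hi


def areas_from_summary(summary: pd.DataFrame, scale: float = 1.0) -> dict[str, SurfaceAreas]:
    """Per-sex :class:`SurfaceAreas` from a cohort summary table.

    The table (as returned by ``load_fixture("morphometrics")``) is
    indexed by sex with columns ``body_area_cm2`` and ``tail_area_cm2``.
    """
    out = {}
    for sex, row in summary.iterrows():
        out[str(sex)] = SurfaceAreas(
            tail_area_cm2=float(row["tail_area_cm2"]) * scale,
            body_area_cm2=float(row["body_area_cm2"]) * scale,
        )
    return out


@dataclass(frozen=True)
class CensusResults:
    """Fitted census: densities, composition, areas, loads and ranges.

    Loads are indexed by sex and region (``tail`` = tail dorsum only,
    ``total`` = body + tail dorsum).  ``baseline_loads`` are unrounded;
    ``load_ranges`` apply quantum rounding and the multiplier range.
    """

    density: DensityEstimate
    prevalence: PrevalenceSummary
    areas: dict[str, SurfaceAreas]
    baseline_loads: dict[str, dict[str, float]]
    load_ranges: dict[str, dict[str, tuple[float, float]]]
    depth: DepthYield | None
    config: RunConfig

    @property
    def composition(self) -> pd.Series | None:
        """Composition fractions, or None when every density is zero."""
        try:
            return self.density.composition
        except EstimationError:
            return None

    @property
    def composition_percent(self) -> pd.Series | None:
        """Composition as whole percentages (half-up); None if undefined."""
        comp = self.composition
        if comp is None:
            return None
        return comp.map(lambda f: round_half_up(100 * f))

    def to_dict(self) -> dict:
        comp = self.composition
        d = {
            "densities_per_cm2": {k: float(v) for k, v in self.density.densities.items()},
            "total_density_per_cm2": self.density.total_density,
            "composition_fraction": (
                None if comp is None else {k: float(v) for k, v in comp.items()}
            ),
            "composition_percent": (
                None
                if comp is None
                else {k: int(v) for k, v in self.composition_percent.items()}
            ),
            "n_hosts": self.density.n_hosts,
            "n_samples": self.density.n_samples,
            "areas_cm2": {
                sex: {
                    "body": a.body_area_cm2,
                    "tail": a.tail_area_cm2,
                    "total": a.total_area_cm2,
                }
                for sex, a in self.areas.items()
            },
            "baseline_loads": {
                sex: {reg: round_half_up(v) for reg, v in regs.items()}
                for sex, regs in self.baseline_loads.items()
            },
            "load_ranges": {
                sex: {reg: list(rng) for reg, rng in regs.items()}
                for sex, regs in self.load_ranges.items()
            },
            "prevalence": {
                "n_hosts": self.prevalence.n_hosts,
                "n_hosts_all_species": self.prevalence.n_hosts_all_species,
                "presence": {
                    host: {sp: bool(v) for sp, v in row.items()}
                    for host, row in self.prevalence.presence.iterrows()
                },
            },
            "provenance": {
                "inclusion_rule": self.density.inclusion_rule,
                "mapping": list(self.config.mapping),
                "multipliers": list(self.config.multipliers),
                "rounding_quantum": self.config.rounding_quantum,
                "config_digest": self.config.digest(),
            },
        }
        if self.depth is not None:
            d["depth_yield"] = {
                "per_host": dict(self.depth.per_host),
                "undefined_hosts": list(self.depth.undefined_hosts),
            }
            if self.depth.per_host:
                d["depth_yield"].update(
                    min=self.depth.min, median=self.depth.median, max=self.depth.max
                )
        return d

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        """Human-readable census report."""
        lines = ["Epibiont census summary", "=" * 23, ""]
        lines.append(
            f"Hosts: {self.density.n_hosts}   samples included: "
            f"{self.density.n_samples}   rule: {self.density.inclusion_rule}"
        )
        lines.append("")
        lines.append("Mean density (nematodes/cm2) and composition:")
        pcts = self.composition_percent
        for sp, d in self.density.densities.items():
            pct = "  —" if pcts is None else f"{int(pcts[sp]):3d}%"
            lines.append(f"  {sp:<12} {d:7.2f}   {pct}")
        lines.append(f"  {'total':<12} {self.density.total_density:7.2f}")
        lines.append("")
        for sex, a in self.areas.items():
            lines.append(
                f"{sex.capitalize()} areas (cm2): body {a.body_area_cm2:,.0f}  "
                f"tail {a.tail_area_cm2:,.0f}  total {a.total_area_cm2:,.0f}"
            )
        lines.append("")
        lines.append("Baseline loads (nematodes) and extrapolated ranges:")
        for sex, regs in self.baseline_loads.items():
            for reg, v in regs.items():
                lo, hi = self.load_ranges[sex][reg]
                lines.append(
                    f"  {sex} {reg:<6} {round_half_up(v):>10,.0f}   "
                    f"range {lo:,.0f}-{hi:,.0f}"
                )
        lines.append("")
        lines.append(
            f"Prevalence: {self.prevalence.n_hosts_all_species} of "
            f"{self.prevalence.n_hosts} hosts positive for all species"
        )
        if self.depth is not None and self.depth.per_host:
            lines.append(
                f"Depth yield over sequential passes: median "
                f"{self.depth.median:.2f}x (range {self.depth.min:.2f}-"
                f"{self.depth.max:.2f}x, n={len(self.depth.per_host)})"
            )
        return "\n".join(lines)


class CensusModel:
    """Census estimator for a scrape-sample survey.

    Parameters
    ----------
    samples : iterable of ScrapeSample
        The survey (all hosts, all plates).
    areas : mapping sex -> SurfaceAreas
        Per-sex dorsal surface areas to extrapolate over.
    config : RunConfig, optional
        Mapping, inclusion rule, multipliers, rounding; defaults
        reproduce the standard 2018 analysis.
    """

    def __init__(
        self,
        samples: Iterable[ScrapeSample],
        areas: Mapping[str, SurfaceAreas],
        config: RunConfig | None = None,
    ) -> None:
        self.samples = list(samples)
        self.areas = dict(areas)
        self.config = config or RunConfig()
        if not self.samples:
            raise ValueError("survey is empty")
        if not self.areas:
            raise ValueError("no surface areas supplied")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_fixture(cls, year: int | str = 2018, config: RunConfig | None = None):
        """Model over a packaged survey fixture, with the published per-sex
        mean areas."""
        samples = records.load_fixture(year)
        cfg = config or RunConfig()
        areas = areas_from_summary(
            records.load_fixture("morphometrics"), scale=cfg.area_scale
        )
        return cls(samples, areas, cfg)

    @classmethod
    def from_tables(
        cls,
        samples_path,
        morphometrics_path,
        config: RunConfig | None = None,
    ):
        """Model from a sample table and a per-individual morphometrics
        table (areas computed with the circle + ellipse model and averaged
        within sex)."""
        cfg = config or RunConfig()
        samples = records.read_sample_table(samples_path)
        morphs = records.read_morphometrics_table(morphometrics_path)
        return cls(samples, cohort_areas(morphs, scale=cfg.area_scale), cfg)

    # -- fitting -----------------------------------------------------------

    def fit(self) -> CensusResults:
        """Run the full estimation pipeline and assemble the results."""
        cfg = self.config
        mapping = CategoryMapping(cfg.mapping)
        estimate = population_mean_density(
            self.samples,
            mapping=mapping,
            rule=cfg.inclusion_rule,
            exclude_hosts=cfg.exclude_hosts,
        )
        prev = prevalence_summary(self.samples)
        D = estimate.total_density
        baseline = {
            sex: {
                "tail": total_load(D, a.tail_area_cm2),
                "total": total_load(D, a.total_area_cm2),
            }
            for sex, a in self.areas.items()
        }
        ranges = {
            sex: {
                reg: load_range(v, cfg.multipliers, cfg.rounding_quantum)
                for reg, v in regs.items()
            }
            for sex, regs in baseline.items()
        }
        try:
            depth = depth_yield(self.samples, mapping)
        except EstimationError:
            depth = None
        return CensusResults(
            density=estimate,
            prevalence=prev,
            areas=self.areas,
            baseline_loads=baseline,
            load_ranges=ranges,
            depth=depth,
            config=cfg,
        )
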