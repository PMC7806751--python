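"""Dorsal surface areas from host morphometrics.

The dorsal surface available to skin epibionts is approximated by two
plane figures: a circle for the tail dorsum, with radius r = G / 2π
derived from the umbilicus girth G, and an ellipse for the body dorsum
with semi-minor axis a = r and semi-major axis b = L / 2, half the
curvilinear total length L.  Hence

    A_tail  = π r²      = G² / 4π
    A_body  = π a b     = G L / 4
    A_total = A_body + A_tail   (exactly, by construction)

Cohort summaries average the per-individual areas (mean of areas, not
area of mean measurements — the formulas are nonlinear in G, so the
order matters).  A configurable ``scale`` factor is provided for
sensitivity analysis of the full-figure reading of "dorsal".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .records import HostMorphometrics

__all__ = [
    "SurfaceAreas",
    "girth_to_radius",
    "tail_dorsal_area",
    "body_dorsal_area",
    "individual_areas",
    "cohort_areas",
]


@dataclass(frozen=True)
class SurfaceAreas:
    """Dorsal area components (cm²) for one host or a cohort mean."""

    tail_area_cm2: float
    body_area_cm2: float
    radius_cm: float | None = None
    semi_major_cm: float | None = None

    def __post_init__(self) -> None:
        if self.tail_area_cm2 <= 0 or self.body_area_cm2 <= 0:
            raise ValueError("areas must be positive")

    @property
    def total_area_cm2(self) -> float:
        """Body + tail, additive by definition."""
        return self.body_area_cm2 + self.tail_area_cm2


def girth_to_radius(girth_cm: float) -> float:
    """Radius (cm) of the circular tail cross-section from girth G: r = G/2π."""
    if not girth_cm > 0:
        raise ValueError(f"girth must be positive, got {girth_cm}")
    return girth_cm / (2.0 * math.pi)


def tail_dorsal_area(girth_cm: float, scale: float = 1.0) -> float:
    """Circular tail dorsum area (cm²): π r² = G²/4π."""
    r = girth_to_radius(girth_cm)
    return scale * math.pi * r * r


def body_dorsal_area(girth_cm: float, length_cm: float, scale: float = 1.0) -> float:
    """Elliptical body dorsum area (cm²): π·(G/2π)·(L/2)."""
    if not length_cm > 0:
        raise ValueError(f"length must be positive, got {length_cm}")
    a = girth_to_radius(girth_cm)
    b = length_cm / 2.0
    return scale * math.pi * a * b


def individual_areas(morph: HostMorphometrics, scale: float = 1.0) -> SurfaceAreas:
    """Surface-area components for one measured individual."""
    return SurfaceAreas(
        tail_area_cm2=tail_dorsal_area(morph.umbilicus_girth_cm, scale),
        body_area_cm2=body_dorsal_area(
            morph.umbilicus_girth_cm, morph.curvilinear_length_cm, scale
        ),
        radius_cm=girth_to_radius(morph.umbilicus_girth_cm),
        semi_major_cm=morph.curvilinear_length_cm / 2.0,
    )


def cohort_areas(
    morphs: Iterable[HostMorphometrics], scale: float = 1.0
) -> dict[str, SurfaceAreas]:
    """Per-sex mean surface areas over a cohort.

    Areas are computed individual by individual and then averaged within
    sex.  Raises on an empty cohort.
    """
    by_sex: dict[str, list[SurfaceAreas]] = {}
    for m in morphs:
        by_sex.setdefault(m.sex, []).append(individual_areas(m, scale))
    if not by_sex:
        raise ValueError("no individuals supplied")
    out: dict[str, SurfaceAreas] = {}
    for sex, areas in by_sex.items():
        n = len(areas)
        out[sex] = SurfaceAreas(
            tail_area_cm2=sum(a.tail_area_cm2 for a in areas) / n,
            body_area_cm2=sum(a.body_area_cm2 for a in areas) / n,
            radius_cm=sum(a.radius_cm for a in areas) / n,
            semi_major_cm=sum(a.semi_major_cm for a in areas) / n,
        )
    return out
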