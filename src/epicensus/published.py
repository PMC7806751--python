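"""Published 2018 survey results used by the verification command.

These are the headline numbers of the original census (densities to
2 decimals, composition in whole percent, loads as printed integers,
ranges at the 10,000 quantum).  ``verify_2018`` recomputes everything
from a fitted :class:`~epicensus.census.CensusResults` and returns an
itemized list of mismatches — empty when the run reproduces the
published analysis.

The 2019 printed density means (2.64/2.65/2.65) are deliberately *not*
checked anywhere: the sample-inclusion rule behind them is ambiguous
and could not be reconstructed.
"""

from __future__ import annotations

from .census import CensusResults, round_half_up

__all__ = ["PUBLISHED_2018", "verify_2018"]

PUBLISHED_2018 = {
    "densities_per_cm2": {"C. manati": 2.26, "LT": 3.19, "ST": 2.76},
    "composition_percent": {"C. manati": 27, "LT": 39, "ST": 34},
    "loads": {
        ("female", "tail"): 30_636,
        ("male", "tail"): 28_211,
        ("female", "total"): 156_452,
        ("male", "total"): 160_727,
    },
    "load_ranges": {"tail": (90_000, 120_000), "total": (480_000, 640_000)},
    "areas_cm2": {
        "female": {"body": 15_320, "tail": 3_730, "total": 19_050},
        "male": {"body": 16_136, "tail": 3_435, "total": 19_571},
    },
    "n_hosts_all_species": 7,
    # loads derive from area means printed to the whole cm², so they are
    # matched to within this relative tolerance rather than exactly
    "load_rtol": 1e-3,
}


def verify_2018(results: CensusResults) -> list[str]:
    """Compare a fitted census against the published 2018 values.

    Returns a list of human-readable mismatch descriptions (empty on
    success).  Densities are compared after half-up rounding to 2
    decimals, composition after rounding to whole percent, loads within
    ±0.1 %, range endpoints and prevalence exactly.
    """
    ref = PUBLISHED_2018
    failures: list[str] = []

    for sp, want in ref["densities_per_cm2"].items():
        if sp not in results.density.densities.index:
            failures.append(f"density: species {sp!r} missing from estimate")
            continue
        got = round_half_up(float(results.density.densities[sp]), 0.01)
        if abs(got - want) > 1e-9:
            failures.append(f"density[{sp}]: got {got:.2f}, published {want:.2f}")

    pct = results.composition_percent
    for sp, want in ref["composition_percent"].items():
        got = None if pct is None or sp not in pct.index else int(pct[sp])
        if got != want:
            failures.append(f"composition[{sp}]: got {got}%, published {want}%")

    for (sex, region), want in ref["loads"].items():
        got = results.baseline_loads.get(sex, {}).get(region)
        if got is None:
            failures.append(f"load[{sex},{region}]: missing")
        elif abs(got - want) > ref["load_rtol"] * want:
            failures.append(
                f"load[{sex},{region}]: got {got:,.0f}, published {want:,} "
                f"(tolerance ±{100 * ref['load_rtol']:.1f}%)"
            )

    for sex in ("female", "male"):
        for region, want in ref["load_ranges"].items():
            got = results.load_ranges.get(sex, {}).get(region)
            if got is None or tuple(got) != want:
                failures.append(
                    f"range[{sex},{region}]: got {got}, published {want}"
                )

    got_prev = results.prevalence.n_hosts_all_species
    if got_prev != ref["n_hosts_all_species"]:
        failures.append(
            f"prevalence: {got_prev} hosts positive for all species, "
            f"published {ref['n_hosts_all_species']}"
        )
    return failures
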