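"""Density, composition, prevalence and depth-yield estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epicensus import (
    PUBLISHED_MAPPING,
    AbundanceCategory,
    CategoryMapping,
    EstimationError,
    category_to_count,
    composition_fractions,
    depth_yield,
    host_mean_density,
    population_mean_density,
    prevalence_summary,
)

from .conftest import SPECIES, make_sample, random_survey


# ---------------------------------------------------------------------------
# category mapping
# ---------------------------------------------------------------------------


def test_mapping_invariants():
    with pytest.raises(ValueError):
        CategoryMapping((1, 10, 50, 100))  # level 0 must be 0
    with pytest.raises(ValueError):
        CategoryMapping((0, 50, 10, 100))  # not monotone


@pytest.mark.parametrize("level,count", [(0, 0), (1, 10), (2, 50), (3, 100)])
def test_category_to_count_standard_map(level, count):
    assert category_to_count(AbundanceCategory(level), PUBLISHED_MAPPING) == count


# ---------------------------------------------------------------------------
# host- and population-level densities
# ---------------------------------------------------------------------------


def test_host_mean_density_saturated(survey_2018):
    """Six plates all at the top class give 100/25 = 4/cm² per species."""
    host = [s for s in survey_2018 if s.host_id == "CCR18-24"]
    dens = host_mean_density(host)
    assert all(abs(d - 4.0) < 1e-12 for d in dens)


def test_host_mean_density_hand_arithmetic(survey_2018):
    """CCR18-22, first species column (0,+,0,0,++,++) -> 110/6/25."""
    host = [s for s in survey_2018 if s.host_id == "CCR18-22"]
    dens = host_mean_density(host)
    assert dens["C. manati"] == pytest.approx(110 / 6 / 25, abs=1e-12)


def test_host_mean_density_all_absent():
    s = make_sample("H", "A", (0, 0, 0))
    assert (host_mean_density([s]) == 0).all()


def test_host_mean_density_empty_after_filter():
    s = make_sample("H", "A-1", (1, 1, 1), pass_index=2, resample=True)
    with pytest.raises(EstimationError, match="no included samples"):
        host_mean_density([s], rule="non_sequential")


def test_population_mean_unweighted_across_hosts():
    """Hosts contribute equally regardless of how many plates they have."""
    a = [make_sample("A", lab, (2, 0, 0)) for lab in "AB"]  # 50/25 = 2.0
    b = [make_sample("B", lab, (3, 0, 0)) for lab in "ABCDEF"]  # 4.0
    est = population_mean_density(a + b)
    assert est.densities["C. manati"] == pytest.approx(3.0)
    assert est.n_hosts == 2 and est.n_samples == 8


def test_population_single_host_degenerates_to_host_mean():
    s = make_sample("H", "A", (1, 2, 3))
    est = population_mean_density([s])
    assert (est.densities == host_mean_density([s])).all()


def test_inclusion_rule_drops_resamples_keeps_first_passes(survey_2018):
    est = population_mean_density(survey_2018, rule="non_sequential")
    kept_20 = est.per_host.loc["CCR18-20"]
    # first passes A-1..D-1 only: species column (0,+++,0,0) -> 100/4/25 = 1.0
    assert kept_20["C. manati"] == pytest.approx(1.0)
    assert est.n_samples == 42


def test_exclude_hosts_rule(survey_2018):
    est = population_mean_density(survey_2018, exclude_hosts=["CCR18-24"])
    assert est.n_hosts == 6
    assert "CCR18-24" not in est.per_host.index


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def _oracle_density(samples, mapping):
    """Independent double-loop two-stage mean (no pandas, no shortcuts)."""
    hosts = {}
    for s in samples:
        hosts.setdefault(s.host_id, []).append(s)
    totals = {sp: 0.0 for sp in SPECIES}
    for plates in hosts.values():
        for sp in SPECIES:
            acc = 0.0
            for p in plates:
                acc += mapping.counts[p.abundances[sp].level] / p.area_cm2
            totals[sp] += acc / len(plates)
    return {sp: totals[sp] / len(hosts) for sp in SPECIES}


def test_two_stage_estimator_matches_brute_force_oracle():
    rng = np.random.default_rng(0)
    for _ in range(100):
        survey = random_survey(rng)
        est = population_mean_density(survey, rule="all_passes")
        oracle = _oracle_density(survey, PUBLISHED_MAPPING)
        for sp in SPECIES:
            assert abs(est.densities[sp] - oracle[sp]) < 1e-12


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

level_grids = st.lists(
    st.lists(
        st.tuples(st.integers(0, 3), st.integers(0, 3), st.integers(0, 3)),
        min_size=1,
        max_size=5,
    ),
    min_size=1,
    max_size=4,
)


@settings(derandomize=True, max_examples=60)
@given(grid=level_grids, data=st.data())
def test_raising_a_category_never_lowers_any_density(grid, data):
    survey = [
        make_sample(f"H{h}", chr(ord("A") + p), levels)
        for h, plates in enumerate(grid)
        for p, levels in enumerate(plates)
    ]
    base = population_mean_density(survey).densities
    idx = data.draw(st.integers(0, len(survey) - 1))
    sp = data.draw(st.sampled_from(SPECIES))
    target = survey[idx]
    lvl = target.abundances[sp].level
    if lvl == 3:
        return
    import dataclasses

    bumped = dict(target.abundances)
    bumped[sp] = AbundanceCategory(lvl + 1)
    survey[idx] = dataclasses.replace(target, abundances=bumped)
    raised = population_mean_density(survey).densities
    assert (raised >= base - 1e-12).all()


@settings(derandomize=True, max_examples=40)
@given(grid=level_grids, lam=st.floats(0.1, 10.0))
def test_scaling_mapping_scales_densities_not_composition(grid, lam):
    survey = [
        make_sample(f"H{h}", chr(ord("A") + p), levels)
        for h, plates in enumerate(grid)
        for p, levels in enumerate(plates)
    ]
    base = population_mean_density(survey, mapping=PUBLISHED_MAPPING)
    scaled = population_mean_density(survey, mapping=PUBLISHED_MAPPING.scaled(lam))
    assert np.allclose(scaled.densities, lam * base.densities, rtol=1e-12)
    if base.total_density > 0:
        assert np.allclose(
            composition_fractions(scaled), composition_fractions(base), rtol=1e-12
        )
        assert composition_fractions(base).sum() == pytest.approx(1.0)


def test_composition_undefined_for_empty_fauna():
    est = population_mean_density([make_sample("H", "A", (0, 0, 0))])
    with pytest.raises(EstimationError, match="undefined"):
        composition_fractions(est)


def test_composition_point_masses():
    import pandas as pd

    frac = composition_fractions(pd.Series({"a": 1.0, "b": 0.0, "c": 0.0}))
    assert list(frac) == [1.0, 0.0, 0.0]


# ---------------------------------------------------------------------------
# prevalence
# ---------------------------------------------------------------------------


def test_prevalence_2018_all_hosts_positive(survey_2018):
    prev = prevalence_summary(survey_2018)
    assert prev.n_hosts == 7
    assert prev.n_hosts_all_species == 7
    assert prev.presence.all().all()


def test_prevalence_2019_juvenile_lacks_short_tail(survey_2019):
    prev = prevalence_summary(survey_2019)
    assert not prev.presence.loc["CCR19-03", "ST"]
    assert prev.positive_sample_counts.loc["CCR19-03", "ST"] == 0
    assert prev.samples_per_host["CCR19-03"] == 4
    assert prev.n_hosts_all_species == 6


def test_prevalence_empty_survey():
    prev = prevalence_summary([])
    assert prev.n_hosts == 0 and prev.n_hosts_all_species == 0


# ---------------------------------------------------------------------------
# depth yield
# ---------------------------------------------------------------------------


def test_depth_yield_saturated_passes():
    plates = [make_sample("H", "A", (3, 3, 3))] + [
        make_sample("H", f"A-{k}", (3, 3, 3), pass_index=k + 1, resample=True)
        for k in range(1, 4)
    ]
    dy = depth_yield(plates)
    assert dy.per_host["H"] == pytest.approx(4.0)


def test_depth_yield_2019_hand_arithmetic(survey_2019):
    dy = depth_yield(survey_2019)
    assert dy.per_host["CCR19-01"] == pytest.approx(1100 / 300)
    # pseudoreplicates B-D of CCR19-02 must stay out of the ratio
    assert dy.per_host["CCR19-02"] == pytest.approx(1050 / 300)
    assert dy.min >= 1.0
    assert "CCR19-03" not in dy.per_host  # never sequentially sampled


def test_depth_yield_zero_first_pass_flagged():
    plates = [
        make_sample("H", "A", (0, 0, 0)),
        make_sample("H", "A-1", (3, 3, 3), pass_index=2, resample=True),
    ]
    dy = depth_yield(plates)
    assert dy.undefined_hosts == ("H",)
    assert dy.per_host == {}


def test_depth_yield_requires_sequential_hosts():
    with pytest.raises(EstimationError, match="sequential"):
        depth_yield([make_sample("H", "A", (1, 1, 1))])
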