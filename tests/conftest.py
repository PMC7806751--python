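import numpy as np
import pytest

from epicensus import AbundanceCategory, ScrapeSample, load_fixture

SPECIES = ["C. manati", "LT", "ST"]


@pytest.fixture(scope="session")
def survey_2018():
    return load_fixture(2018)


@pytest.fixture(scope="session")
def survey_2019():
    return load_fixture(2019)


@pytest.fixture(scope="session")
def morph_summary():
    return load_fixture("morphometrics")


def make_sample(host, label, levels, pass_index=1, resample=False, area=25.0):
    """Tiny helper: a plate with the given per-species levels."""
    return ScrapeSample(
        host_id=host,
        sample_label=label,
        pass_index=pass_index,
        is_sequential_resample=resample,
        area_cm2=area,
        abundances={sp: AbundanceCategory(lv) for sp, lv in zip(SPECIES, levels)},
    )


def random_survey(rng, max_hosts=5, max_plates=6):
    """A random small pseudoreplicate survey for oracle comparisons."""
    samples = []
    for h in range(rng.integers(1, max_hosts + 1)):
        for p in range(rng.integers(1, max_plates + 1)):
            levels = rng.integers(0, 4, size=len(SPECIES))
            samples.append(make_sample(f"H{h}", chr(ord("A") + p), levels))
    return samples
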