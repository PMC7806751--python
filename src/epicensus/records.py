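"""Survey records: ordinal scrape samples, host morphometrics, tabular I/O.

A scrape sample is one agar plate holding everything scraped from one
5 x 5 cm patch of host skin.  Each morphospecies on the plate is scored on
the ordinal visible-count scale 0 / + / ++ / +++ rather than counted
exactly, so the sample record stores an :class:`AbundanceCategory` per
species together with the sampling metadata (depth pass, resample flag,
visible skin remnants) needed by the estimators downstream.

Two field surveys of Florida manatees (2018: pseudoreplicate plates per
host; 2019: sequential increasing-pressure passes over one patch) ship as
packaged fixtures, hand-transcribed and audit-validated against the
published density means.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "AbundanceCategory",
    "ScrapeSample",
    "HostMorphometrics",
    "ParseError",
    "parse_abundance_symbol",
    "read_sample_table",
    "write_sample_table",
    "read_morphometrics_table",
    "load_fixture",
    "infer_pass_index",
    "species_order",
    "DEFAULT_VISIBLE_RANGES",
    "CAPTION_VISIBLE_RANGES",
]

#: Symbol <-> ordinal level correspondence for the relative-abundance scale.
SYMBOL_TO_LEVEL = {"0": 0, "+": 1, "++": 2, "+++": 3}
LEVEL_TO_SYMBOL = {v: k for k, v in SYMBOL_TO_LEVEL.items()}

#: Visible-count ranges per level from the survey protocol
#: (non-overlapping; used as the simulator's binning default).
DEFAULT_VISIBLE_RANGES: dict[int, tuple[int, int | None]] = {
    0: (0, 0),
    1: (1, 20),
    2: (21, 99),
    3: (100, None),
}

#: The table captions print slightly different (overlapping) ranges for the
#: middle classes; kept for reference alongside each fixture.
CAPTION_VISIBLE_RANGES: dict[int, tuple[int, int | None]] = {
    0: (0, 0),
    1: (1, 15),
    2: (15, 99),
    3: (100, None),
}


class ParseError(ValueError):
    """Raised when a survey table cell or column cannot be interpreted."""


@dataclass(frozen=True, order=True)
class AbundanceCategory:
    """One ordinal relative-abundance class (0, +, ++ or +++)."""

    level: int

    def __post_init__(self) -> None:
        if self.level not in (0, 1, 2, 3):
            raise ValueError(f"abundance level must be 0..3, got {self.level!r}")

    @property
    def symbol(self) -> str:
        return LEVEL_TO_SYMBOL[self.level]

    @property
    def visible_range(self) -> tuple[int, int | None]:
        """Inclusive visible-count range attached to this level.

        Level 0 is exactly (0, 0); the top level is unbounded above.
        """
        return DEFAULT_VISIBLE_RANGES[self.level]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.symbol


def parse_abundance_symbol(token: str) -> AbundanceCategory:
    """Parse a relative-abundance symbol ("0", "+", "++", "+++").

    Whitespace around the token is ignored.  Raises :class:`ParseError`
    for anything else.
    """
    stripped = str(token).strip()
    try:
        return AbundanceCategory(SYMBOL_TO_LEVEL[stripped])
    except KeyError:
        raise ParseError(
            f"unknown abundance symbol {token!r}; expected one of 0, +, ++, +++"
        ) from None


_SUFFIX_RE = re.compile(r"^(?P<base>.*?)-(?P<k>\d+)$")


def infer_pass_index(sample_label: str) -> int:
    """Fallback depth-pass index from a sample label.

    Labels with a ``-k`` numeric suffix (``A-1``, ``A-2`` ...) yield ``k``;
    plain letters yield 1.  Only used when an input table lacks an explicit
    ``pass_index`` column — sequential designs that label the first pass
    with a bare letter must provide the column.
    """
    m = _SUFFIX_RE.match(str(sample_label).strip())
    return int(m.group("k")) if m else 1


def base_label(sample_label: str) -> str:
    """Sample-area label with any ``-k`` pass suffix stripped (A-2 -> A)."""
    m = _SUFFIX_RE.match(str(sample_label).strip())
    return m.group("base") if m else str(sample_label).strip()


@dataclass(frozen=True)
class ScrapeSample:
    """One plate: ordinal abundance per morphospecies plus sampling metadata.

    Parameters
    ----------
    host_id : str
        Host identifier, e.g. ``CCR18-19``.
    sample_label : str
        Plate label within the host (``A``, ``B``, ``A-1`` ...).
    pass_index : int
        Depth order within one 5 x 5 cm area; 1 = first (superficial) pass.
    is_sequential_resample : bool
        True for repeat scrapes of the same area at increased pressure.
    area_cm2 : float
        Scraped skin area, 25 cm² under the standard protocol.
    abundances : dict
        Morphospecies name -> :class:`AbundanceCategory`.
    skin_remnants : bool
        Visible skin remnants present on the plate.
    """

    host_id: str
    sample_label: str
    abundances: dict[str, AbundanceCategory]
    year: int | None = None
    pass_index: int = 1
    is_sequential_resample: bool = False
    area_cm2: float = 25.0
    skin_remnants: bool = False

    def __post_init__(self) -> None:
        if self.area_cm2 <= 0:
            raise ValueError(f"area_cm2 must be positive, got {self.area_cm2}")
        if self.pass_index < 1:
            raise ValueError(f"pass_index must be >= 1, got {self.pass_index}")
        if not self.is_sequential_resample and self.pass_index != 1:
            raise ValueError(
                "pass_index must be 1 for non-resample plates "
                f"({self.host_id}/{self.sample_label} has pass {self.pass_index})"
            )

    @property
    def base_label(self) -> str:
        return base_label(self.sample_label)


@dataclass(frozen=True)
class HostMorphometrics:
    """Body measurements of one host feeding the surface-area model.

    ``curvilinear_length_cm`` is total body length measured along the
    dorsal contour; ``umbilicus_girth_cm`` is the circumference at navel
    level.  Tail length is carried for completeness but unused by the
    area formulas.
    """

    host_id: str
    sex: str
    curvilinear_length_cm: float
    umbilicus_girth_cm: float
    tail_length_cm: float | None = None

    #: Configurable sanity ceiling on girth, to catch unit errors (mm vs cm).
    girth_ceiling_cm: float = field(default=1000.0, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        for name in ("curvilinear_length_cm", "umbilicus_girth_cm"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.tail_length_cm is not None and not self.tail_length_cm > 0:
            raise ValueError("tail_length_cm must be positive when given")
        if self.umbilicus_girth_cm >= self.girth_ceiling_cm:
            raise ValueError(
                f"umbilicus girth {self.umbilicus_girth_cm} cm exceeds the "
                f"sanity ceiling {self.girth_ceiling_cm} cm — check units"
            )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("host_id", "sample_label", "species", "category")
_TRUE_TOKENS = {"true", "1", "yes", "y", "t", "p", "present"}
_FALSE_TOKENS = {"false", "0", "no", "n", "a", "absent", ""}


def _parse_flag(value: object, *, column: str, where: str) -> bool:
    token = str(value).strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise ParseError(f"cannot interpret {column}={value!r} at {where}")


def read_sample_table(path_or_buffer) -> list[ScrapeSample]:
    """Read a long-format scrape-sample table (TSV or CSV, auto-detected).

    One input row per (plate, species); rows sharing (host_id,
    sample_label) are assembled into one :class:`ScrapeSample`.  Input
    order of plates and of species within a plate is preserved.

    Required columns: host_id, sample_label, species, category.
    Optional: year, pass_index, is_resample, area_cm2, skin_remnants.
    """
    df = pd.read_csv(path_or_buffer, sep=None, engine="python", dtype=str)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"sample table is missing required columns: {missing}")

    samples: list[ScrapeSample] = []
    seen_plates: dict[tuple[str, str], int] = {}
    for (host, label), plate in df.groupby(
        ["host_id", "sample_label"], sort=False
    ):
        dup = plate["species"].str.strip().duplicated()
        if dup.any():
            dup_species = plate["species"][dup].iloc[0]
            raise ParseError(
                f"duplicate entry for species {dup_species!r} on plate "
                f"{host}/{label}"
            )
        first = plate.iloc[0]
        abundances: dict[str, AbundanceCategory] = {}
        for _, row in plate.iterrows():
            where = f"host {host}, sample {label}, species {row['species']}"
            try:
                abundances[row["species"].strip()] = parse_abundance_symbol(
                    row["category"]
                )
            except ParseError as exc:
                raise ParseError(f"{exc} ({where})") from None
        where = f"host {host}, sample {label}"
        pass_index = (
            int(first["pass_index"])
            if "pass_index" in plate.columns
            else infer_pass_index(label)
        )
        samples.append(
            ScrapeSample(
                host_id=str(host).strip(),
                sample_label=str(label).strip(),
                year=(
                    int(float(first["year"]))
                    if "year" in plate.columns and not pd.isna(first["year"])
                    else None
                ),
                pass_index=pass_index,
                is_sequential_resample=(
                    _parse_flag(first["is_resample"], column="is_resample", where=where)
                    if "is_resample" in plate.columns
                    else pass_index > 1
                ),
                area_cm2=(
                    float(first["area_cm2"]) if "area_cm2" in plate.columns else 25.0
                ),
                abundances=abundances,
                skin_remnants=(
                    _parse_flag(
                        first["skin_remnants"], column="skin_remnants", where=where
                    )
                    if "skin_remnants" in plate.columns
                    else False
                ),
            )
        )
        seen_plates[(host, label)] = len(samples)
    return samples


def samples_to_frame(samples: Iterable[ScrapeSample]) -> pd.DataFrame:
    """Long-format DataFrame view of a sample collection (one row per
    plate x species), in the standard column order."""
    rows = []
    for s in samples:
        for species, cat in s.abundances.items():
            rows.append(
                {
                    "host_id": s.host_id,
                    "year": s.year,
                    "sample_label": s.sample_label,
                    "pass_index": s.pass_index,
                    "is_resample": s.is_sequential_resample,
                    "area_cm2": s.area_cm2,
                    "species": species,
                    "category": cat.symbol,
                    "skin_remnants": s.skin_remnants,
                }
            )
    return pd.DataFrame(rows)


def write_sample_table(samples: Iterable[ScrapeSample], path) -> None:
    """Write samples as a TSV that :func:`read_sample_table` round-trips."""
    samples_to_frame(samples).to_csv(path, sep="\t", index=False)


def read_morphometrics_table(path_or_buffer, **kwargs) -> list[HostMorphometrics]:
    """Read a per-individual morphometrics table (columns: id, sex,
    curvilinear_length_cm, umbilicus_girth_cm, tail_length_cm)."""
    df = pd.read_csv(path_or_buffer, sep=None, engine="python")
    needed = {"id", "sex", "curvilinear_length_cm", "umbilicus_girth_cm"}
    missing = needed - set(df.columns)
    if missing:
        raise ParseError(f"morphometrics table is missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        tail = row.get("tail_length_cm")
        out.append(
            HostMorphometrics(
                host_id=str(row["id"]),
                sex=str(row["sex"]).strip().lower(),
                curvilinear_length_cm=float(row["curvilinear_length_cm"]),
                umbilicus_girth_cm=float(row["umbilicus_girth_cm"]),
                tail_length_cm=None if pd.isna(tail) else float(tail),
                **kwargs,
            )
        )
    return out


def write_morphometrics_table(morphs: Iterable[HostMorphometrics], path) -> None:
    pd.DataFrame(
        {
            "id": m.host_id,
            "sex": m.sex,
            "curvilinear_length_cm": m.curvilinear_length_cm,
            "umbilicus_girth_cm": m.umbilicus_girth_cm,
            "tail_length_cm": m.tail_length_cm,
        }
        for m in morphs
    ).to_csv(path, sep="\t", index=False)


def species_order(samples: Iterable[ScrapeSample]) -> list[str]:
    """Morphospecies names in first-appearance order across a survey."""
    order: list[str] = []
    for s in samples:
        for sp in s.abundances:
            if sp not in order:
                order.append(sp)
    return order


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

_FIXTURE_FILES = {
    "2018": "table1_2018.tsv",
    "2019": "table2_2019.tsv",
    "morphometrics": "morphometrics_summary.tsv",
}


def fixture_path(name: str) -> Path:
    key = str(name)
    if key not in _FIXTURE_FILES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURE_FILES)}"
        )
    return Path(resources.files("epicensus").joinpath("data", _FIXTURE_FILES[key]))


def load_fixture(name):
    """Load a packaged survey fixture.

    ``2018`` / ``2019`` (int or str) return the transcribed scrape-sample
    tables for the respective field season as a list of
    :class:`ScrapeSample`.  ``"morphometrics"`` returns the per-sex summary
    of the published adult morphometrics (mean curvilinear length, tail
    length and the three dorsal-area means, in cm / cm²) as a DataFrame
    indexed by sex.

    The sample fixtures are hand transcriptions; the 2018 one is validated
    by the density audit in the test suite (it reproduces the published
    per-species means to 2 decimals under the standard mapping and
    inclusion rule), which pins down the typographically ambiguous cells.
    """
    key = str(name)
    path = fixture_path(key)
    if key == "morphometrics":
        return pd.read_csv(path, sep="\t").set_index("sex")
    return read_sample_table(path)
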