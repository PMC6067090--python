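"""Reading and writing the WHO Mortality Database ICD-10 flat-file dialect.

The mortality files ("Morticd10"-style) are comma-delimited with a header row
and one row per (country, year, cause, sex) combination.  Deaths are spread
over 26 age-group columns (all-ages total, age 0, single years 1-4, 5-year
groups 5-9 ... 95+, unknown age) plus four infant columns covering the first
year of life: [0,1) day, [1,7) days, [7,28) days and [28,365) days.  Only
rows whose format codes indicate that detailed infant breakdown are usable
for trajectory construction; the four first-year age categories are
mandatory for the analysis downstream.

Population denominators come from a separate pair of delimited tables:
single-year-of-age living counts (ages 0-94) and live births per
country-year.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CauseSet",
    "DeathRecord",
    "PopulationTable",
    "NINE_COUNTRIES",
    "parse_cause_range",
    "read_deaths",
    "write_deaths",
    "read_population",
    "write_population",
]

#: Default country configuration: WHO numeric country codes for the nine
#: European countries pooled by the analysis, with the calendar spans in
#: which ICD-10 and the detailed infant age categories are in use.
NINE_COUNTRIES: Mapping[str, tuple[str, range]] = {
    "Denmark": ("4050", range(1994, 2010)),
    "Finland": ("4070", range(1996, 2016)),
    "Norway": ("4220", range(1996, 2016)),
    "Sweden": ("4290", range(1997, 2016)),
    "Austria": ("4010", range(2002, 2017)),
    "Czech Republic": ("4045", range(1994, 2016)),
    "Hungary": ("4150", range(1996, 2016)),
    "Poland": ("4230", range(1999, 2016)),
    "Slovakia": ("4274", range(1996, 2015)),
}

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}$")
_CODE4_RE = re.compile(r"^[A-Z][0-9]{2}[0-9]?$")

# Column layout of the dialect.  Deaths1 is the all-ages total; Deaths2 is
# age 0; Deaths3-6 are single years 1-4; Deaths7-24 are 5-year groups
# 5-9 ... 90-94; Deaths25 is 95+; Deaths26 is unknown age.  IM_Deaths1-4 are
# the four infant categories.
_HEADER = (
    ["Country", "Admin1", "SubDiv", "Year", "List", "Cause", "Sex", "Frmat", "IM_Frmat"]
    + [f"Deaths{i}" for i in range(1, 27)]
    + [f"IM_Deaths{i}" for i in range(1, 5)]
)

#: Age format code signalling the full age detail (single years to 4,
#: 5-year groups to 95+) and infant format code signalling the four
#: first-year categories.
DETAILED_FRMAT = "00"
DETAILED_IM_FRMAT = "01"


@dataclass(frozen=True)
class CauseSet:
    """A named set of 3-character ICD-10 codes; name "ALL" means no filtering."""

    name: str
    codes: frozenset[str]

    def __post_init__(self) -> None:
        if self.name != "ALL":
            if not self.codes:
                raise ValueError("empty cause set (only 'ALL' may be empty)")
            bad = [c for c in self.codes if not _CODE_RE.match(c)]
            if bad:
                raise ValueError(f"malformed ICD-10 codes: {sorted(bad)}")

    def __contains__(self, code: str) -> bool:
        return self.name == "ALL" or code in self.codes


ALL_CAUSES = CauseSet("ALL", frozenset())
CACNS = None  # assigned below once parse_cause_range exists
DNS = None


@dataclass
class DeathRecord:
    """One dialect row: deaths by age column for a (country, year, cause, sex).

    ``deaths`` holds the 26 age-group columns in dialect order and
    ``infant_deaths`` the four first-year columns.  When both format codes
    are detailed, the infant columns must sum to the age-0 column.
    """

    country: str
    year: int
    cause: str
    sex: int  # 1 male, 2 female, 9 unspecified
    deaths: list[int]
    infant_deaths: list[int]
    age_format: str = DETAILED_FRMAT
    infant_format: str = DETAILED_IM_FRMAT
    admin1: str = ""
    subdiv: str = ""
    icd_list: str = "103"

    def __post_init__(self) -> None:
        if len(self.deaths) != 26:
            raise ValueError("deaths must have 26 age-group columns")
        if len(self.infant_deaths) != 4:
            raise ValueError("infant_deaths must have 4 columns")
        if any(d < 0 for d in self.deaths + self.infant_deaths):
            raise ValueError("negative death count")

    @property
    def has_infant_detail(self) -> bool:
        return (
            self.age_format == DETAILED_FRMAT
            and self.infant_format == DETAILED_IM_FRMAT
        )

    def validate_infant_consistency(self) -> None:
        if self.has_infant_detail and sum(self.infant_deaths) != self.deaths[1]:
            raise ValueError(
                f"infant columns sum to {sum(self.infant_deaths)} but age-0 "
                f"column is {self.deaths[1]} "
                f"({self.country}/{self.year}/{self.cause}/sex={self.sex})"
            )


def parse_cause_range(spec: str) -> CauseSet:
    """Expand an ICD-10 range spec like ``"Q00-Q07"`` into a :class:`CauseSet`.

    Accepts a single 3-character code, a hyphenated inclusive range whose
    endpoints share the letter prefix, or a comma-separated list of these.
    ``"ALL"`` disables cause filtering.
    """
    spec = spec.strip()
    if spec.upper() == "ALL":
        return ALL_CAUSES
    codes: set[str] = set()
    for part in spec.split(","):
        part = part.strip().upper()
        if "-" in part:
            start, _, end = part.partition("-")
            start, end = start.strip(), end.strip()
            for c in (start, end):
                if not _CODE_RE.match(c):
                    raise ValueError(f"malformed ICD-10 code {c!r} in {part!r}")
            if start[0] != end[0]:
                raise ValueError(
                    f"range endpoints {start!r}-{end!r} have different letter prefixes"
                )
            lo, hi = int(start[1:]), int(end[1:])
            if lo > hi:
                raise ValueError(f"reversed range {part!r} (start > end)")
            codes.update(f"{start[0]}{i:02d}" for i in range(lo, hi + 1))
        else:
            if not _CODE_RE.match(part):
                raise ValueError(f"malformed ICD-10 code {part!r}")
            codes.add(part)
    return CauseSet(spec, frozenset(codes))


CACNS = parse_cause_range("Q00-Q07")
DNS = parse_cause_range("G00-G99")


@dataclass
class ReadDeathsResult:
    """Filtered usable records plus 1-based line numbers of unusable rows."""

    records: list[DeathRecord]
    unusable_lines: list[int] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _open(source) -> io.TextIOBase:
    if hasattr(source, "read"):
        return source
    return open(source, "r", newline="")


def read_deaths(
    source,
    causes: CauseSet = ALL_CAUSES,
    countries: Iterable[str] | None = None,
    years: Iterable[int] | None = None,
) -> ReadDeathsResult:
    """Read dialect rows, filter by cause/country/year, and validate.

    Four-character causes are retained when their 3-character prefix is in
    ``causes`` and are tallied under that prefix.  Rows whose format codes
    lack the four infant columns are reported in ``unusable_lines`` rather
    than silently dropped.  ``countries`` defaults to the nine configured
    country codes; ``years`` defaults to each country's configured span.
    """
    default_years: dict[str, range] | None = None
    if countries is None:
        countries = {code for code, _ in NINE_COUNTRIES.values()}
        if years is None:
            default_years = {code: yrs for code, yrs in NINE_COUNTRIES.values()}
    countries = set(countries)
    yearset = set(years) if years is not None else None

    fh = _open(source)
    close = not hasattr(source, "read")
    try:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            return ReadDeathsResult([])
        if [h.strip() for h in header] != _HEADER:
            raise ValueError("unrecognized header: not the expected WHO dialect")
        records: list[DeathRecord] = []
        unusable: list[int] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(_HEADER):
                raise ValueError(f"line {lineno}: expected {len(_HEADER)} fields, got {len(row)}")
            country, admin1, subdiv, year_s, lst, cause, sex_s, frmat, im_frmat = (
                c.strip() for c in row[:9]
            )
            try:
                year = int(year_s)
                sex = int(sex_s)
                counts = [int(c) if c.strip() else 0 for c in row[9:]]
            except ValueError as exc:
                raise ValueError(f"line {lineno}: malformed numeric field ({exc})") from None
            if country not in countries:
                continue
            if yearset is not None:
                if year not in yearset:
                    continue
            elif default_years is not None and year not in default_years[country]:
                continue
            cause = cause.upper()
            if not _CODE4_RE.match(cause):
                raise ValueError(f"line {lineno}: malformed cause code {cause!r}")
            prefix = cause[:3]
            if prefix not in causes:
                continue
            rec = DeathRecord(
                country=country,
                year=year,
                cause=prefix,
                sex=sex,
                deaths=counts[:26],
                infant_deaths=counts[26:30],
                age_format=frmat,
                infant_format=im_frmat,
                admin1=admin1,
                subdiv=subdiv,
                icd_list=lst,
            )
            if not rec.has_infant_detail:
                unusable.append(lineno)
                continue
            try:
                rec.validate_infant_consistency()
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
            records.append(rec)
        return ReadDeathsResult(records, unusable)
    finally:
        if close:
            fh.close()


def write_deaths(records: Sequence[DeathRecord], sink) -> None:
    """Write records in the dialect; inverse of :func:`read_deaths`."""
    fh = sink if hasattr(sink, "write") else open(sink, "w", newline="")
    close = not hasattr(sink, "write")
    try:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for r in records:
            writer.writerow(
                [r.country, r.admin1, r.subdiv, r.year, r.icd_list, r.cause, r.sex,
                 r.age_format, r.infant_format]
                + list(r.deaths)
                + list(r.infant_deaths)
            )
    finally:
        if close:
            fh.close()


class PopulationTable:
    """Single-year-of-age living counts (0-94) and live births per country-year."""

    N_AGES = 95

    def __init__(self) -> None:
        self._pop: dict[tuple[str, int], list[int]] = {}
        self._births: dict[tuple[str, int], int] = {}

    def add(self, country: str, year: int, age: int, count: int) -> None:
        if not 0 <= age < self.N_AGES:
            raise ValueError(f"age {age} outside 0-{self.N_AGES - 1}")
        if count < 0:
            raise ValueError("negative population count")
        key = (country, year)
        ages = self._pop.setdefault(key, [-1] * self.N_AGES)
        if ages[age] >= 0:
            raise ValueError(f"duplicate population entry for {key} age {age}")
        ages[age] = count

    def set_births(self, country: str, year: int, births: int) -> None:
        if births < 0:
            raise ValueError("negative live births")
        self._births[(country, year)] = births

    def country_years(self) -> list[tuple[str, int]]:
        return sorted(self._pop)

    def population(self, country: str, year: int, age: int) -> int:
        return self._pop[(country, year)][age]

    def births(self, country: str, year: int) -> int:
        return self._births[(country, year)]

    def has(self, country: str, year: int) -> bool:
        return (country, year) in self._pop

    def validate(self) -> None:
        """Every country-year must cover ages 0-94 and have live births."""
        for key, ages in self._pop.items():
            missing = [a for a, c in enumerate(ages) if c < 0]
            if missing:
                raise ValueError(
                    f"population for {key} missing ages "
                    f"{_format_gaps(missing)}"
                )
            if key not in self._births:
                raise ValueError(f"live births missing for {key}")


def _format_gaps(missing: list[int]) -> str:
    runs, start = [], missing[0]
    prev = start
    for a in missing[1:]:
        if a != prev + 1:
            runs.append((start, prev))
            start = a
        prev = a
    runs.append((start, prev))
    return ", ".join(f"{a}" if a == b else f"{a}-{b}" for a, b in runs)


def read_population(pop_source, births_source) -> PopulationTable:
    """Read single-year population counts and live births.

    ``pop_source``: comma-delimited Country,Year,Age,Pop with header;
    ``births_source``: comma-delimited Country,Year,LiveBirths with header.
    Validates that every country-year covers ages 0-94 exactly once.
    """
    table = PopulationTable()
    fh = _open(pop_source)
    close = not hasattr(pop_source, "read")
    try:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip() for h in header] != ["Country", "Year", "Age", "Pop"]:
            raise ValueError("unrecognized population header")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                country, year, age, count = row[0].strip(), int(row[1]), int(row[2]), int(row[3])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"population line {lineno}: malformed row ({exc})") from None
            table.add(country, year, age, count)
    finally:
        if close:
            fh.close()
    fh = _open(births_source)
    close = not hasattr(births_source, "read")
    try:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip() for h in header] != ["Country", "Year", "LiveBirths"]:
            raise ValueError("unrecognized live-births header")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                table.set_births(row[0].strip(), int(row[1]), int(row[2]))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"live-births line {lineno}: malformed row ({exc})") from None
    finally:
        if close:
            fh.close()
    table.validate()
    return table


def write_population(table: PopulationTable, pop_sink, births_sink) -> None:
    """Write a :class:`PopulationTable` back to the two delimited files."""
    fh = pop_sink if hasattr(pop_sink, "write") else open(pop_sink, "w", newline="")
    close = not hasattr(pop_sink, "write")
    try:
        writer = csv.writer(fh)
        writer.writerow(["Country", "Year", "Age", "Pop"])
        for country, year in table.country_years():
            for age in range(PopulationTable.N_AGES):
                writer.writerow([country, year, age, table.population(country, year, age)])
    finally:
        if close:
            fh.close()
    fh = births_sink if hasattr(births_sink, "write") else open(births_sink, "w", newline="")
    close = not hasattr(births_sink, "write")
    try:
        writer = csv.writer(fh)
        writer.writerow(["Country", "Year", "LiveBirths"])
        for country, year in table.country_years():
            writer.writerow([country, year, table.births(country, year)])
    finally:
        if close:
            fh.close()
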