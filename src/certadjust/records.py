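"""Death-record data model, ICD-10 cause grouping and study-population filters.

The unit of analysis is one registered death with its full certificate
content: every ICD-10 code reported in part 1 (conditions directly leading
to death) or part 2 (other significant contributing conditions), plus the
single underlying cause of death (UCOD) selected by coding rules.  A death
is a *dementia MCOD* death when a dementia code (F00, F01, F03, G30, G31)
appears anywhere on the certificate and the decedent was aged 50 or more;
it is additionally a *dementia UCOD* death when the UCOD itself is a
dementia code.

Cause grouping is driven by a :class:`CauseTaxonomy` — an ordered mapping
from group names to ICD-10 code intervals, shipped as editable YAML rather
than hard-coded, so the comorbid groups can be matched to any national
grouping scheme.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional

import yaml

logger = logging.getLogger(__name__)

#: Ordered 5-year age bands used throughout; the study population is 50+.
AGE_GROUPS: tuple[str, ...] = (
    "50-54", "55-59", "60-64", "65-69", "70-74",
    "75-79", "80-84", "85-89", "90-94", "95+",
)
_AGE_INDEX = {a: i for i, a in enumerate(AGE_GROUPS)}

SEXES: tuple[str, ...] = ("male", "female")

#: Dementia at 3-character ICD-10 resolution: Alzheimer disease (F00, G30),
#: vascular dementia (F01), other specified dementias (G31), unspecified (F03).
DEMENTIA_CODES: frozenset[str] = frozenset({"F00", "F01", "F03", "G30", "G31"})

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[0-9]?$")


def normalize_code(code: str) -> str:
    """Uppercase, strip the decimal point, validate the ICD-10 lexical form.

    Raises ``ValueError`` naming the offending string for anything that is
    not letter + two digits (+ optional sub-code digit).
    """
    c = str(code).strip().upper().replace(".", "")
    if not _CODE_RE.match(c):
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    return c


def code_root(code: str) -> str:
    """3-character root of a (normalized) ICD-10 code; 4-character codes
    inherit their parent's group."""
    return normalize_code(code)[:3]


def _root_to_int(root: str) -> int:
    return (ord(root[0]) - ord("A")) * 100 + int(root[1:3])


def _int_to_root(n: int) -> str:
    return chr(ord("A") + n // 100) + f"{n % 100:02d}"


def expand_interval(spec: str) -> list[str]:
    """Expand ``"I20-I25"`` (or a single code like ``"N39"``) into the list
    of 3-character roots it covers.  Intervals may span letters (V01-Y89)."""
    spec = spec.strip().upper()
    if "-" in spec:
        lo, hi = (code_root(p) for p in spec.split("-", 1))
    else:
        lo = hi = code_root(spec)
    a, b = _root_to_int(lo), _root_to_int(hi)
    if a > b:
        raise ValueError(f"interval bounds out of order: {spec!r}")
    return [_int_to_root(i) for i in range(a, b + 1)]


class CauseTaxonomy:
    """Ordered mapping from named cause groups to ICD-10 code intervals.

    The ``dementia`` group is fixed by the study definition; all other
    groups must be pairwise disjoint so that :meth:`classify` is unique.
    Cardiovascular disease (I00–I99) is exposed as a derived super-group via
    :meth:`is_cvd` because it deliberately spans several comorbid groups.
    """

    CVD_RANGE = (_root_to_int("I00"), _root_to_int("I99"))

    def __init__(self, groups: dict[str, list[str]]):
        self.groups: dict[str, list[str]] = dict(groups)
        if "dementia" not in self.groups:
            raise ValueError("taxonomy must define a 'dementia' group")
        dem = set()
        for spec in self.groups["dementia"]:
            dem.update(expand_interval(spec))
        if dem != set(DEMENTIA_CODES):
            raise ValueError(
                f"dementia group must be exactly {sorted(DEMENTIA_CODES)}, got {sorted(dem)}"
            )
        self._lookup: dict[str, str] = {}
        for name, specs in self.groups.items():
            if name == "dementia":
                continue
            for spec in specs:
                for root in expand_interval(spec):
                    other = self._lookup.get(root)
                    if other is not None and other != name:
                        raise ValueError(
                            f"groups {other!r} and {name!r} overlap at {root}"
                        )
                    self._lookup[root] = name
        # dementia wins over any other grouping of its roots
        for root in DEMENTIA_CODES:
            self._lookup[root] = "dementia"

    @property
    def group_names(self) -> list[str]:
        return list(self.groups)

    @property
    def comorbid_groups(self) -> list[str]:
        """All group names except dementia, in declaration order."""
        return [g for g in self.groups if g != "dementia"]

    def classify(self, code: str) -> Optional[str]:
        """Group containing the code's 3-character root, or ``None``."""
        return self._lookup.get(code_root(code))

    def is_dementia(self, code: str) -> bool:
        return code_root(code) in DEMENTIA_CODES

    def is_cvd(self, code: str) -> bool:
        """Whether the code falls in the cardiovascular range I00–I99."""
        return self.CVD_RANGE[0] <= _root_to_int(code_root(code)) <= self.CVD_RANGE[1]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CauseTaxonomy":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls({name: [str(s) for s in specs] for name, specs in raw.items()})

    @classmethod
    def default(cls) -> "CauseTaxonomy":
        """Taxonomy shipped with the package (see ``data/default_taxonomy.yaml``)."""
        ref = resources.files("certadjust.data").joinpath("default_taxonomy.yaml")
        raw = yaml.safe_load(ref.read_text())
        return cls({name: [str(s) for s in specs] for name, specs in raw.items()})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.groups, fh, sort_keys=False)


def classify_code(code: str, taxonomy: CauseTaxonomy) -> Optional[str]:
    """Classify one ICD-10 code; malformed input raises ``ValueError``."""
    return taxonomy.classify(code)


@dataclass
class DeathRecord:
    """One registered death as reported on the international certificate."""

    record_id: str
    year: int
    sex: str
    age_group: str
    part1_codes: list[str]
    part2_codes: list[str]
    ucod_code: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex label: {self.sex!r}")
        if self.age_group not in _AGE_INDEX:
            raise ValueError(f"age group outside study bands: {self.age_group!r}")
        self.part1_codes = [normalize_code(c) for c in self.part1_codes]
        self.part2_codes = [normalize_code(c) for c in self.part2_codes]
        self.ucod_code = normalize_code(self.ucod_code)
        # transcription noise: a code listed in both parts is kept in part 1
        p1 = set(self.part1_codes)
        self.part2_codes = [c for c in self.part2_codes if c not in p1]
        if not self.part1_codes and not self.part2_codes:
            raise ValueError(f"record {self.record_id}: no causes reported")

    @property
    def all_codes(self) -> list[str]:
        return self.part1_codes + self.part2_codes


def is_dementia_mcod(record: DeathRecord) -> bool:
    """Dementia reported anywhere on the certificate, decedent aged 50+.

    Age below the study bands is rejected at parse time, so within the data
    model this reduces to the certificate-content check.
    """
    return any(code_root(c) in DEMENTIA_CODES for c in record.all_codes)


def is_dementia_ucod(record: DeathRecord) -> bool:
    """The selected underlying cause is itself a dementia code."""
    return code_root(record.ucod_code) in DEMENTIA_CODES


@dataclass
class Cohort:
    """A collection of death records for one country."""

    records: list[DeathRecord]
    country_label: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[DeathRecord]:
        return iter(self.records)

    @property
    def year_range(self) -> tuple[int, int]:
        years = [r.year for r in self.records]
        return (min(years), max(years)) if years else (0, 0)

    @property
    def years(self) -> list[int]:
        return sorted({r.year for r in self.records})


_COLUMNS = ("record_id", "year", "sex", "age_group", "part1", "part2", "ucod")


def _split_codes(cell: str) -> list[str]:
    return [c for c in str(cell).split(";") if c.strip()] if cell else []


def load_records(path: str | Path, country_label: str = "") -> Cohort:
    """Read the canonical MCOD CSV (see package docs for the dialect).

    Any malformed row fails loudly with its 1-based data row number.
    """
    records: list[DeathRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
        for i, row in enumerate(reader, start=1):
            try:
                records.append(
                    DeathRecord(
                        record_id=row["record_id"],
                        year=int(row["year"]),
                        sex=row["sex"],
                        age_group=row["age_group"],
                        part1_codes=_split_codes(row["part1"]),
                        part2_codes=_split_codes(row["part2"]),
                        ucod_code=row["ucod"],
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}, row {i}: {exc}") from exc
    logger.info("loaded %d records from %s", len(records), path)
    return Cohort(records=records, country_label=country_label)


def write_records(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort back to the canonical CSV dialect."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for r in cohort:
            writer.writerow(
                [
                    r.record_id,
                    r.year,
                    r.sex,
                    r.age_group,
                    ";".join(r.part1_codes),
                    ";".join(r.part2_codes),
                    r.ucod_code,
                ]
            )
    logger.info("wrote %d records to %s", len(cohort), path)


def filter_dementia_mcod(cohort: Cohort) -> Cohort:
    """Restrict to deaths with dementia reported anywhere on the certificate.

    Idempotent; the number of dropped records is logged.  An empty result is
    a warning, not an error — a valid (if useless) study population.
    """
    kept = [r for r in cohort if is_dementia_mcod(r)]
    dropped = len(cohort) - len(kept)
    if dropped:
        logger.info("filter_dementia_mcod: dropped %d of %d records", dropped, len(cohort))
    if not kept:
        logger.warning("filter_dementia_mcod: empty cohort after filtering")
    return Cohort(records=kept, country_label=cohort.country_label)
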