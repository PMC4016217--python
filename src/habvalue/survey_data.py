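"""Survey-table readers and per-site occupancy series.

Three public-archive dialects are supported, all comma-separated with a
header row:

``portal``
    site_id, year, substrate, status, n_breeding_birds, n_nests,
    n_fledglings — annual site-occupancy plus colony-level reproduction.
``hamilton``
    colony_id, year, substrate, n_breeding_birds, n_fledglings, rss,
    prop_successful — reproductive-success records only.
``statewide``
    record_id, year, substrate, n_birds — colony records used for decadal
    frequency and size summaries.

Substrate strings are normalised to a small enumeration through a
data-driven synonym map so archive spellings ("Cattails", "triticale",
"grain") need no code changes.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "Status",
    "SUBSTRATES",
    "SurveyRecord",
    "OccupancySeries",
    "ValidationReport",
    "SchemaError",
    "ConflictError",
    "read_survey_table",
    "write_portal_table",
    "build_occupancy_series",
    "normalize_substrate",
    "load_config",
]

STUDY_WINDOW = (1980, 2011)

#: Canonical substrate labels. "other:<label>" is used for anything not in
#: the synonym map so rare substrates survive the minimum-records filter
#: downstream instead of being silently merged.
SUBSTRATES = (
    "cattail-marsh",
    "bulrush",
    "blackberry",
    "nettle",
    "thistle",
    "grain-field",
    "mustard",
    "willow",
)

DEFAULT_SYNONYMS: dict[str, str] = {
    "cattail": "cattail-marsh",
    "cattails": "cattail-marsh",
    "cattail marsh": "cattail-marsh",
    "cattail-marsh": "cattail-marsh",
    "typha": "cattail-marsh",
    "marsh": "cattail-marsh",
    "bulrush": "bulrush",
    "tule": "bulrush",
    "schoenoplectus": "bulrush",
    "blackberry": "blackberry",
    "himalayan blackberry": "blackberry",
    "rubus": "blackberry",
    "nettle": "nettle",
    "nettles": "nettle",
    "stinging nettle": "nettle",
    "thistle": "thistle",
    "thistles": "thistle",
    "milk thistle": "thistle",
    "bull thistle": "thistle",
    "grain": "grain-field",
    "grain field": "grain-field",
    "grain-field": "grain-field",
    "grain fields": "grain-field",
    "triticale": "grain-field",
    "silage": "grain-field",
    "wheat": "grain-field",
    "mustard": "mustard",
    "willow": "willow",
    "willows": "willow",
}

_SCHEMA_COLUMNS: dict[str, list[str]] = {
    "portal": ["site_id", "year", "substrate", "status"],
    "hamilton": ["colony_id", "year", "substrate"],
    "statewide": ["record_id", "year", "substrate", "n_birds"],
}


class Status(str, enum.Enum):
    """Annual breeding status of a site.

    ``unknown`` means the site was not surveyed that year; it is never a
    statement about the birds.
    """

    OCCUPIED = "occupied"
    UNOCCUPIED = "unoccupied"
    UNKNOWN = "unknown"


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


class ConflictError(ValueError):
    """Contradictory statuses recorded for the same site and year."""


def normalize_substrate(raw: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Map a raw substrate string onto the canonical enumeration.

    Matching is case-insensitive after whitespace stripping; unmatched
    labels become ``other:<lowercased label>``.
    """
    table = DEFAULT_SYNONYMS if synonyms is None else synonyms
    key = str(raw).strip().lower()
    if not key:
        return "other:unspecified"
    return table.get(key, key if key in SUBSTRATES else f"other:{key}")


def load_config(path: str | Path) -> dict:
    """Read a YAML config holding synonym maps and the study window."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "synonyms" in cfg:
        cfg["synonyms"] = {
            str(k).strip().lower(): v for k, v in cfg["synonyms"].items()
        }
    return cfg


@dataclass(frozen=True)
class SurveyRecord:
    """One site (or colony) in one year, from one of the three archives."""

    site_id: str
    year: int
    substrate: str
    status: Status
    n_breeding_birds: float | None = None
    n_nests: float | None = None
    n_fledglings: float | None = None
    rss: float | None = None
    prop_successful: float | None = None
    dataset_tag: str = "portal"

    def __post_init__(self) -> None:
        lo, hi = STUDY_WINDOW
        if not lo <= self.year <= hi:
            raise ValueError(f"year {self.year} outside study window {STUDY_WINDOW}")
        for name in ("n_breeding_birds", "n_nests", "n_fledglings"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass
class ValidationReport:
    """Bookkeeping for a table read: what parsed, what was dropped."""

    n_records: int = 0
    n_duplicates_dropped: int = 0
    n_unparseable: int = 0
    issues: Counter = field(default_factory=Counter)

    @property
    def n_input_rows(self) -> int:
        return self.n_records + self.n_duplicates_dropped + self.n_unparseable


@dataclass
class OccupancySeries:
    """Year-by-year status map for one site on one substrate.

    Years inside the observation span but missing from the input appear as
    ``unknown``; years outside the span are absent entirely.
    """

    site_id: str
    substrate: str
    statuses: dict[int, Status]

    def __post_init__(self) -> None:
        self.statuses = dict(sorted(self.statuses.items()))

    @property
    def years(self) -> list[int]:
        return list(self.statuses)

    @property
    def span(self) -> tuple[int, int]:
        ys = self.years
        return ys[0], ys[-1]

    def n_unknown(self) -> int:
        return sum(1 for s in self.statuses.values() if s is Status.UNKNOWN)


def _parse_status(raw: object) -> Status:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return Status.UNKNOWN
    text = str(raw).strip().lower()
    if text in ("", "nan", "na", "unknown", "not surveyed"):
        return Status.UNKNOWN
    if text in ("occupied", "occ", "1", "yes", "present", "true"):
        return Status.OCCUPIED
    if text in ("unoccupied", "unocc", "0", "no", "absent", "false"):
        return Status.UNOCCUPIED
    raise ValueError(f"unrecognised status {raw!r}")


def _opt_float(row: pd.Series, col: str) -> float | None:
    if col not in row or pd.isna(row[col]):
        return None
    return float(row[col])


def read_survey_table(
    path: str | Path,
    schema: str,
    synonyms: Mapping[str, str] | None = None,
) -> tuple[list[SurveyRecord], ValidationReport]:
    """Read one archive table into validated :class:`SurveyRecord` rows.

    Rows whose year or counts fail to parse are skipped and counted in the
    :class:`ValidationReport`; exact duplicate (site, year) rows collapse to
    one record. A missing mandatory column raises :class:`SchemaError`
    naming the column.
    """
    if schema not in _SCHEMA_COLUMNS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(_SCHEMA_COLUMNS)}")
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in _SCHEMA_COLUMNS[schema]:
        if col not in df.columns:
            raise SchemaError(f"schema {schema!r} requires column {col!r}")

    id_col = {"portal": "site_id", "hamilton": "colony_id", "statewide": "record_id"}[schema]
    report = ValidationReport()
    records: list[SurveyRecord] = []
    seen: dict[tuple[str, int], SurveyRecord] = {}

    for _, row in df.iterrows():
        try:
            year = int(float(row["year"]))
        except (TypeError, ValueError):
            report.n_unparseable += 1
            report.issues["bad_year"] += 1
            continue
        substrate = normalize_substrate(row.get("substrate", ""), synonyms)
        try:
            if schema == "portal":
                rec = SurveyRecord(
                    site_id=str(row[id_col]),
                    year=year,
                    substrate=substrate,
                    status=_parse_status(row.get("status")),
                    n_breeding_birds=_opt_float(row, "n_breeding_birds"),
                    n_nests=_opt_float(row, "n_nests"),
                    n_fledglings=_opt_float(row, "n_fledglings"),
                    dataset_tag="portal",
                )
            elif schema == "hamilton":
                rec = SurveyRecord(
                    site_id=str(row[id_col]),
                    year=year,
                    substrate=substrate,
                    status=Status.OCCUPIED,  # reproduction implies breeding
                    n_breeding_birds=_opt_float(row, "n_breeding_birds"),
                    n_fledglings=_opt_float(row, "n_fledglings"),
                    rss=_opt_float(row, "rss"),
                    prop_successful=_opt_float(row, "prop_successful"),
                    dataset_tag="hamilton",
                )
            else:
                rec = SurveyRecord(
                    site_id=str(row[id_col]),
                    year=year,
                    substrate=substrate,
                    status=Status.OCCUPIED,
                    n_breeding_birds=_opt_float(row, "n_birds"),
                    dataset_tag="statewide",
                )
        except ValueError:
            report.n_unparseable += 1
            report.issues["bad_row"] += 1
            continue

        key = (rec.site_id, rec.year)
        if schema != "statewide" and key in seen:
            if seen[key] == rec:
                report.n_duplicates_dropped += 1
                continue
            # conflicting duplicates surface downstream in series building
        records.append(rec)
        seen[key] = rec
        report.n_records += 1
    return records, report


def write_portal_table(records: Iterable[SurveyRecord], path: str | Path) -> None:
    """Write records back out in the portal schema (round-trip support)."""
    rows = []
    for r in records:
        rows.append(
            {
                "site_id": r.site_id,
                "year": r.year,
                "substrate": r.substrate,
                "status": "" if r.status is Status.UNKNOWN else r.status.value,
                "n_breeding_birds": r.n_breeding_birds,
                "n_nests": r.n_nests,
                "n_fledglings": r.n_fledglings,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def _collapse_visits(statuses: Sequence[Status]) -> Status:
    # occupied if ANY visit found breeding birds, else unoccupied if at
    # least one visit found none, else unknown
    if Status.OCCUPIED in statuses:
        return Status.OCCUPIED
    if Status.UNOCCUPIED in statuses:
        return Status.UNOCCUPIED
    return Status.UNKNOWN


def build_occupancy_series(
    records: Iterable[SurveyRecord],
    on_conflict: str = "collapse",
) -> list[OccupancySeries]:
    """Assemble one occupancy series per site (per substrate run).

    Multiple rows for one (site, year) are treated as within-season visits
    and collapse to a single annual status (occupied wins over unoccupied
    wins over unknown) when ``on_conflict="collapse"`` (the default: a
    colony found breeding on any visit makes the year occupied). With
    ``on_conflict="error"`` contradictory known statuses raise
    :class:`ConflictError` listing the conflict. A site whose substrate
    changes between years is split into one series per consecutive
    substrate run, because turnover and longevity are substrate-specific;
    conflicting substrate labels within one year always raise.
    """
    if on_conflict not in ("collapse", "error"):
        raise ValueError("on_conflict must be 'collapse' or 'error'")
    by_site: dict[str, dict[int, list[SurveyRecord]]] = {}
    for rec in records:
        by_site.setdefault(rec.site_id, {}).setdefault(rec.year, []).append(rec)

    out: list[OccupancySeries] = []
    for site_id, years in sorted(by_site.items()):
        annual: dict[int, tuple[Status, str]] = {}
        for year, recs in sorted(years.items()):
            known = {r.status for r in recs} - {Status.UNKNOWN}
            if on_conflict == "error" and len(known) > 1:
                raise ConflictError(
                    f"site {site_id!r} year {year}: conflicting statuses "
                    f"{sorted(s.value for s in known)}"
                )
            status = _collapse_visits([r.status for r in recs])
            substrates = {r.substrate for r in recs if r.status is not Status.UNKNOWN}
            if len(substrates) > 1:
                raise ConflictError(
                    f"site {site_id!r} year {year}: conflicting substrates {sorted(substrates)}"
                )
            substrate = substrates.pop() if substrates else recs[0].substrate
            annual[year] = (status, substrate)

        # split into substrate runs; unknown years inherit the running substrate
        yrs = sorted(annual)
        lo, hi = yrs[0], yrs[-1]
        runs: list[tuple[str, dict[int, Status]]] = []
        current_sub: str | None = None
        current: dict[int, Status] = {}
        for year in range(lo, hi + 1):
            status, sub = annual.get(year, (Status.UNKNOWN, current_sub or ""))
            if status is Status.UNKNOWN:
                if current_sub is not None:
                    current[year] = Status.UNKNOWN
                continue
            if current_sub is None:
                current_sub = sub
            elif sub != current_sub:
                runs.append((current_sub, current))
                current_sub, current = sub, {}
            current[year] = status
        if current_sub is not None:
            runs.append((current_sub, current))

        n_runs = len(runs)
        for i, (sub, statuses) in enumerate(runs):
            # trim trailing unknowns (they belong to no substrate run)
            ys = sorted(statuses)
            while ys and statuses[ys[-1]] is Status.UNKNOWN:
                statuses.pop(ys.pop())
            if not statuses:
                continue
            sid = site_id if n_runs == 1 else f"{site_id}#{i}"
            out.append(OccupancySeries(site_id=sid, substrate=sub, statuses=statuses))
    return out
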