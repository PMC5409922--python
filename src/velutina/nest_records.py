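"""Record-level nest data: parsing, activity classification and yearly tallies.

A discovered *Vespa velutina* nest is either a primary nest (the small
foundress nest, active until roughly the end of July, after which the colony
has moved on) or a secondary nest (the large permanent nest, active until the
foundresses disperse to hibernate in mid-November).  Whether destroying a
discovered nest actually removed a living colony therefore depends on the
calendar date of destruction, which is what :func:`classify_activity`
encodes.  Yearly tallies and the colony-counting rule (active-destroyed
primaries plus all secondaries) are computed by :func:`tally_yearly` and
:func:`detected_colonies`.
"""
from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

logger = logging.getLogger(__name__)

__all__ = [
    "Stage",
    "StructureClass",
    "Activity",
    "ActivityCutoffs",
    "NestRecord",
    "YearlyCounts",
    "ParseError",
    "RowError",
    "classify_structure",
    "classify_activity",
    "parse_records",
    "tally_yearly",
    "detected_colonies",
    "read_counts_csv",
    "write_counts_csv",
]


class Stage(str, Enum):
    PRIMARY = "primary"
    SECONDARY = "secondary"
    UNKNOWN = "unknown"


class StructureClass(str, Enum):
    NATURAL = "natural"
    MAN_MADE = "man_made"
    UNKNOWN = "unknown"


class Activity(str, Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"
    NOT_DESTROYED = "not_destroyed"


#: Genus tokens accepted in structure descriptions such as "oak tree".
TREE_GENERA = frozenset({
    "oak", "pine", "plane", "poplar", "alder", "cedar", "locust",
    "birch", "tulip", "acacia", "lime", "sweetgum", "fir",
})

#: Natural structures that are not genus-labelled trees.
NATURAL_TOKENS = frozenset({
    "tree", "tree stump", "bush", "hedge", "bamboo", "bank", "magnolia bush",
})

MAN_MADE_TOKENS = frozenset({
    "building", "manhole cover", "ventilation grill", "road sign",
    "birdhouse", "electricity pylon", "other man-made",
})


@dataclass(frozen=True)
class ActivityCutoffs:
    """Calendar cut-offs separating active from abandoned nests.

    Primary nests destroyed after the end of July, and secondary (or
    stage-unrecorded) nests destroyed after the middle of November, are
    treated as inactive: their colony had already moved on or released its
    foundresses, so the destruction removed no reproduction.  Both cut-offs
    are inclusive on the active side and configurable.
    """

    primary_cutoff: tuple[int, int] = (7, 31)
    secondary_cutoff: tuple[int, int] = (11, 15)

    def __post_init__(self) -> None:
        for name in ("primary_cutoff", "secondary_cutoff"):
            month, day = getattr(self, name)
            date(2000, month, day)  # validates month/day
        if self.primary_cutoff >= self.secondary_cutoff:
            raise ValueError("primary_cutoff must fall before secondary_cutoff")


DEFAULT_CUTOFFS = ActivityCutoffs()


def classify_structure(text: Optional[str]) -> tuple[StructureClass, Optional[str]]:
    """Map a free-text structure description to (class, tree genus).

    Recognised vocabulary: genus-labelled trees ("oak tree", "pine tree", ...),
    plain natural structures (tree, tree stump, bush, hedge, bamboo, bank) and
    man-made structures (building, manhole cover, ...).  Unmapped text yields
    ``UNKNOWN`` with a logged warning; absent text yields ``UNKNOWN`` silently.
    """
    if text is None or not text.strip():
        return StructureClass.UNKNOWN, None
    token = " ".join(text.strip().lower().split())
    if token in MAN_MADE_TOKENS:
        return StructureClass.MAN_MADE, None
    if token in NATURAL_TOKENS:
        return StructureClass.NATURAL, None
    if token.endswith(" tree"):
        genus = token[: -len(" tree")]
        if genus in TREE_GENERA:
            return StructureClass.NATURAL, genus
    if token in TREE_GENERA:
        return StructureClass.NATURAL, token
    logger.warning("unrecognised structure description %r -> unknown", text)
    return StructureClass.UNKNOWN, None


def classify_activity(
    stage: Stage,
    date_destroyed: Optional[date],
    cutoffs: ActivityCutoffs = DEFAULT_CUTOFFS,
) -> Activity:
    """Classify whether a nest was destroyed while its colony was alive.

    The rule is purely calendar-based: a primary nest destroyed on or before
    the primary cut-off (default 31 July) was active; a secondary nest — or
    one of unrecorded stage — destroyed on or before the secondary cut-off
    (default 15 November) was active.  A missing destruction date means the
    nest was never destroyed.
    """
    if date_destroyed is None:
        return Activity.NOT_DESTROYED
    day = (date_destroyed.month, date_destroyed.day)
    cutoff = (
        cutoffs.primary_cutoff if stage is Stage.PRIMARY else cutoffs.secondary_cutoff
    )
    return Activity.ACTIVE if day <= cutoff else Activity.INACTIVE


@dataclass(frozen=True)
class NestRecord:
    """One discovered nest."""

    year: int
    date_found: date
    date_destroyed: Optional[date]
    stage: Stage
    structure_text: Optional[str] = None
    structure_class: StructureClass = StructureClass.UNKNOWN
    tree_genus: Optional[str] = None
    activity_at_destruction: Activity = Activity.NOT_DESTROYED

    def __post_init__(self) -> None:
        if self.date_destroyed is not None and self.date_destroyed < self.date_found:
            raise ValueError(
                f"destruction date {self.date_destroyed} precedes discovery "
                f"date {self.date_found}"
            )
        if self.tree_genus is not None and self.structure_class is not StructureClass.NATURAL:
            raise ValueError("a tree genus implies a natural structure")

    @classmethod
    def build(
        cls,
        year: int,
        date_found: date,
        date_destroyed: Optional[date],
        stage: Stage,
        structure_text: Optional[str] = None,
        cutoffs: ActivityCutoffs = DEFAULT_CUTOFFS,
    ) -> "NestRecord":
        """Construct a record, deriving structure class, genus and activity."""
        structure_class, genus = classify_structure(structure_text)
        text = structure_text.strip() if structure_text and structure_text.strip() else None
        return cls(
            year=year,
            date_found=date_found,
            date_destroyed=date_destroyed,
            stage=stage,
            structure_text=text,
            structure_class=structure_class,
            tree_genus=genus,
            activity_at_destruction=classify_activity(stage, date_destroyed, cutoffs),
        )

    @property
    def is_tree(self) -> bool:
        """True if the nest sat in/on a tree (genus-labelled, plain, or stump)."""
        if self.tree_genus is not None:
            return True
        if self.structure_text is None:
            return False
        token = " ".join(self.structure_text.lower().split())
        return token in ("tree", "tree stump")


@dataclass(frozen=True)
class YearlyCounts:
    """Per-year nest tallies (one printed table row).

    ``n_active_unclassified_destroyed`` carries the active-destroyed nests of
    years in which stage was not recorded; those years have all nests in
    ``n_unclassified``.
    """

    year: int
    n_detected_total: int
    n_primary: int
    n_secondary: int
    n_unclassified: int
    n_active_primary_destroyed: int
    n_active_secondary_destroyed: int
    n_active_unclassified_destroyed: int = 0

    def __post_init__(self) -> None:
        if self.n_primary + self.n_secondary + self.n_unclassified != self.n_detected_total:
            raise ValueError(f"{self.year}: stage counts do not sum to the total")
        if self.n_active_primary_destroyed > self.n_primary:
            raise ValueError(f"{self.year}: more active primaries destroyed than primaries")
        if self.n_active_secondary_destroyed > self.n_secondary:
            raise ValueError(f"{self.year}: more active secondaries destroyed than secondaries")
        if self.n_active_unclassified_destroyed > self.n_unclassified:
            raise ValueError(f"{self.year}: more active unclassified destroyed than unclassified")
        for name in (
            "n_detected_total", "n_primary", "n_secondary", "n_unclassified",
            "n_active_primary_destroyed", "n_active_secondary_destroyed",
            "n_active_unclassified_destroyed",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.year}: negative count {name}")

    @property
    def n_inactive_secondary_detected(self) -> int:
        return self.n_secondary - self.n_active_secondary_destroyed

    @property
    def stage_recorded(self) -> bool:
        return self.n_unclassified == 0


class ParseError(ValueError):
    """Raised when a record CSV contains unparseable mandatory fields."""

    def __init__(self, errors: Sequence["RowError"]):
        self.errors = list(errors)
        lines = "; ".join(str(e) for e in self.errors[:10])
        more = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
        super().__init__(f"{len(self.errors)} bad row(s): {lines}{more}")


@dataclass(frozen=True)
class RowError:
    row: int  # 1-based data-row index
    fieldname: str
    message: str

    def __str__(self) -> str:
        return f"row {self.row}, field '{self.fieldname}': {self.message}"


_STAGE_TOKENS = {
    "primary": Stage.PRIMARY,
    "secondary": Stage.SECONDARY,
    "unknown": Stage.UNKNOWN,
    "": Stage.UNKNOWN,
}

#: Sentinel values meaning "never destroyed" in the destruction-date column.
_NO_DESTRUCTION = {"", "0", "na", "none"}


def _parse_date(token: str) -> date:
    return date.fromisoformat(token.strip())


def parse_records(
    source: Union[str, Path, TextIO],
    cutoffs: ActivityCutoffs = DEFAULT_CUTOFFS,
    collect_errors: bool = False,
):
    """Parse a record-level nest CSV into :class:`NestRecord` objects.

    Expected columns: ``year, date_found, date_destroyed, stage, structure``
    (comma-separated, UTF-8, ISO-8601 dates, header row required).  The
    destruction date accepts the sentinel ``0`` (or blank) for nests never
    destroyed.  With ``collect_errors=True`` returns ``(records, errors)``
    instead of raising :class:`ParseError` on bad rows; good rows are kept
    either way.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return parse_records(fh, cutoffs=cutoffs, collect_errors=collect_errors)

    reader = csv.DictReader(source)
    records: list[NestRecord] = []
    errors: list[RowError] = []
    for i, row in enumerate(reader, start=1):
        try:
            year = int(str(row["year"]).strip())
        except (KeyError, ValueError, TypeError):
            errors.append(RowError(i, "year", f"not an integer: {row.get('year')!r}"))
            continue
        try:
            found = _parse_date(row["date_found"])
        except (KeyError, ValueError, TypeError):
            errors.append(RowError(i, "date_found", f"malformed date: {row.get('date_found')!r}"))
            continue
        raw_destroyed = str(row.get("date_destroyed") or "").strip().lower()
        if raw_destroyed in _NO_DESTRUCTION:
            destroyed: Optional[date] = None
        else:
            try:
                destroyed = _parse_date(raw_destroyed)
            except ValueError:
                errors.append(RowError(i, "date_destroyed", f"malformed date: {raw_destroyed!r}"))
                continue
        stage_token = str(row.get("stage") or "").strip().lower()
        if stage_token not in _STAGE_TOKENS:
            errors.append(RowError(i, "stage", f"unknown stage token: {stage_token!r}"))
            continue
        try:
            rec = NestRecord.build(
                year=year,
                date_found=found,
                date_destroyed=destroyed,
                stage=_STAGE_TOKENS[stage_token],
                structure_text=row.get("structure"),
                cutoffs=cutoffs,
            )
        except ValueError as exc:
            errors.append(RowError(i, "record", str(exc)))
            continue
        records.append(rec)

    if collect_errors:
        return records, errors
    if errors:
        raise ParseError(errors)
    return records


def tally_yearly(
    records: Iterable[NestRecord],
    cutoffs: ActivityCutoffs = DEFAULT_CUTOFFS,
) -> list[YearlyCounts]:
    """Aggregate records into one :class:`YearlyCounts` per calendar year.

    Activity is re-derived from the destruction dates under ``cutoffs``, so
    the tally is a pure function of (records, cutoffs) and permutation
    invariant in the records.
    """
    acc: dict[int, dict[str, int]] = {}
    for rec in records:
        c = acc.setdefault(rec.year, {
            "total": 0, "primary": 0, "secondary": 0, "unclassified": 0,
            "ap": 0, "as": 0, "au": 0,
        })
        c["total"] += 1
        activity = classify_activity(rec.stage, rec.date_destroyed, cutoffs)
        if rec.stage is Stage.PRIMARY:
            c["primary"] += 1
            if activity is Activity.ACTIVE:
                c["ap"] += 1
        elif rec.stage is Stage.SECONDARY:
            c["secondary"] += 1
            if activity is Activity.ACTIVE:
                c["as"] += 1
        else:
            c["unclassified"] += 1
            if activity is Activity.ACTIVE:
                c["au"] += 1
    return [
        YearlyCounts(
            year=year,
            n_detected_total=c["total"],
            n_primary=c["primary"],
            n_secondary=c["secondary"],
            n_unclassified=c["unclassified"],
            n_active_primary_destroyed=c["ap"],
            n_active_secondary_destroyed=c["as"],
            n_active_unclassified_destroyed=c["au"],
        )
        for year, c in sorted(acc.items())
    ]


def detected_colonies(counts: YearlyCounts) -> int:
    """Number of distinct colonies evidenced by one year's detections.

    A colony occupies a primary then a secondary nest, so colonies are counted
    as active-destroyed primaries (colonies killed before building a
    secondary) plus all detected secondaries.  For years in which stage was
    never recorded the raw nest total stands in for the colony count.  A mixed
    year (some records staged, some not) counts its unclassified nests as
    secondaries — the conservative assumption — with a warning.
    """
    if not counts.stage_recorded:
        if counts.n_primary or counts.n_secondary:
            warnings.warn(
                f"{counts.year}: {counts.n_unclassified} unclassified nests in a "
                "year with staged nests; counting them as secondary",
                stacklevel=2,
            )
            return (
                counts.n_active_primary_destroyed
                + counts.n_secondary
                + counts.n_unclassified
            )
        return counts.n_detected_total
    return counts.n_active_primary_destroyed + counts.n_secondary


_COUNT_COLUMNS = [
    "year", "n_detected_total", "n_primary", "n_secondary", "n_unclassified",
    "n_active_primary_destroyed", "n_active_secondary_destroyed",
    "n_active_unclassified_destroyed",
]


def read_counts_csv(source: Union[str, Path, TextIO]) -> list[YearlyCounts]:
    """Read a yearly-counts CSV (columns as written by :func:`write_counts_csv`)."""
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return read_counts_csv(fh)
    out = []
    for row in csv.DictReader(source):
        kwargs = {k: int(row.get(k) or 0) for k in _COUNT_COLUMNS}
        out.append(YearlyCounts(**kwargs))
    return sorted(out, key=lambda c: c.year)


def write_counts_csv(counts: Sequence[YearlyCounts], target: Union[str, Path, TextIO]) -> None:
    if isinstance(target, (str, Path)):
        with open(target, "w", encoding="utf-8", newline="") as fh:
            write_counts_csv(counts, fh)
        return
    writer = csv.writer(target)
    writer.writerow(_COUNT_COLUMNS + ["n_detected_colonies"])
    for c in sorted(counts, key=lambda c: c.year):
        writer.writerow([getattr(c, k) for k in _COUNT_COLUMNS] + [detected_colonies(c)])
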