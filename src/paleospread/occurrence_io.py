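"""Reading, validating, cleaning and time-binning of fossil occurrence tables.

The expected input is a PaleoDB-style download: one row per occurrence, with
an accepted taxon name and rank, a collection (locality) identifier, a
reference (publication) identifier, palaeocoordinates, and the age bounds of
the interval the occurrence is dated to.  Column names are configurable via
:class:`Dialect`; the defaults mirror PaleoDB download headers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "TaxonRank",
    "OccurrenceRecord",
    "TimeBin",
    "PoolDiagnostics",
    "Dialect",
    "RowError",
    "FilterConfig",
    "read_occurrence_table",
    "write_occurrence_table",
    "apply_taxon_filters",
    "collapse_duplicates",
    "load_bin_scheme",
    "default_bin_scheme",
    "assign_time_bins",
    "pool_diagnostics",
    "reference_threshold_filter",
    "write_cleaning_report",
]

#: Flags an occurrence may carry; each maps to one cleaning filter.
KNOWN_FLAGS = frozenset(
    {"marine", "flying", "ichno", "oo", "soft_tissue", "wastebasket"}
)


class TaxonRank(str, Enum):
    SPECIES = "species"
    GENUS = "genus"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class OccurrenceRecord:
    """One fossil occurrence: a taxon recorded at a collection."""

    occurrence_id: str
    taxon_name: str
    taxon_rank: TaxonRank
    collection_id: str
    reference_id: str
    palaeolat: float
    palaeolon: float
    interval_max_ma: float
    interval_min_ma: float
    flags: frozenset = frozenset()
    time_bin: str | None = None

    def validate(self) -> list[str]:
        problems = []
        if not self.occurrence_id or not self.collection_id or not self.reference_id:
            problems.append("empty identifier")
        if not -90.0 <= self.palaeolat <= 90.0:
            problems.append(f"palaeolat {self.palaeolat} outside [-90, 90]")
        if not -180.0 < self.palaeolon <= 180.0:
            problems.append(f"palaeolon {self.palaeolon} outside (-180, 180]")
        if self.interval_min_ma < 0:
            problems.append("interval_min_ma negative")
        if self.interval_max_ma < self.interval_min_ma:
            problems.append("interval_max_ma < interval_min_ma")
        unknown = self.flags - KNOWN_FLAGS
        if unknown:
            problems.append(f"unknown flags {sorted(unknown)}")
        return problems


@dataclass(frozen=True)
class TimeBin:
    """A named geological interval; ages in Ma, start older than end."""

    name: str
    start_ma: float
    end_ma: float

    def __post_init__(self) -> None:
        if not self.start_ma > self.end_ma:
            raise ValueError(f"bin {self.name}: start_ma must exceed end_ma")

    @property
    def duration_myr(self) -> float:
        return self.start_ma - self.end_ma

    @property
    def midpoint_ma(self) -> float:
        return 0.5 * (self.start_ma + self.end_ma)

    def contains(self, max_ma: float, min_ma: float) -> bool:
        """Closed-interval containment: the occurrence's age range must fall
        entirely within the bin (boundary-equal ages count as inside)."""
        return max_ma <= self.start_ma and min_ma >= self.end_ma


@dataclass(frozen=True)
class PoolDiagnostics:
    """Sampling-effort summary of one occurrence pool."""

    n_occurrences: int
    n_collections: int
    n_references: int
    raw_richness: int
    goods_u: float | None  # None when undefined (empty pool)
    dominance: float | None


@dataclass(frozen=True)
class RowError:
    row: int
    message: str


@dataclass(frozen=True)
class Dialect:
    """Column mapping from a CSV header to occurrence fields.

    Defaults follow PaleoDB download headers.  ``flag_columns`` maps flag
    names to columns holding truthy markers (non-empty / non-zero means the
    flag is set); absent columns simply yield no flags.
    """

    occurrence_id: str = "occurrence_no"
    collection_id: str = "collection_no"
    taxon_name: str = "accepted_name"
    taxon_rank: str = "accepted_rank"
    palaeolat: str = "paleolat"
    palaeolon: str = "paleolng"
    reference_id: str = "reference_no"
    interval_max_ma: str = "max_ma"
    interval_min_ma: str = "min_ma"
    flag_columns: Mapping[str, str] = field(
        default_factory=lambda: {f: f"flag_{f}" for f in sorted(KNOWN_FLAGS)}
    )

    @property
    def mandatory(self) -> list[str]:
        return [
            self.occurrence_id,
            self.collection_id,
            self.taxon_name,
            self.taxon_rank,
            self.palaeolat,
            self.palaeolon,
            self.reference_id,
            self.interval_max_ma,
            self.interval_min_ma,
        ]


_TRUTHY = {"1", "true", "t", "yes", "y"}


def _parse_rank(raw: str) -> TaxonRank:
    raw = raw.strip().lower()
    if raw in ("species", "subspecies"):
        return TaxonRank.SPECIES
    if raw == "genus":
        return TaxonRank.GENUS
    return TaxonRank.INDETERMINATE


def read_occurrence_table(
    path: str | Path, dialect: Dialect | None = None
) -> tuple[list[OccurrenceRecord], list[RowError]]:
    """Read a CSV of occurrences; returns (records, row_errors).

    Malformed rows are collected as :class:`RowError` with 1-based data row
    numbers, never silently dropped.  A missing mandatory column raises
    ``ValueError`` (a configuration error, not a data error).
    """
    dialect = dialect or Dialect()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in dialect.mandatory if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {missing}")

    records: list[OccurrenceRecord] = []
    errors: list[RowError] = []
    flag_cols = {f: c for f, c in dialect.flag_columns.items() if c in df.columns}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        try:
            flags = frozenset(
                f
                for f, c in flag_cols.items()
                if str(row[c]).strip().lower() in _TRUTHY
            )
            rec = OccurrenceRecord(
                occurrence_id=str(row[dialect.occurrence_id]).strip(),
                taxon_name=str(row[dialect.taxon_name]).strip(),
                taxon_rank=_parse_rank(str(row[dialect.taxon_rank])),
                collection_id=str(row[dialect.collection_id]).strip(),
                reference_id=str(row[dialect.reference_id]).strip(),
                palaeolat=float(row[dialect.palaeolat]),
                palaeolon=float(row[dialect.palaeolon]),
                interval_max_ma=float(row[dialect.interval_max_ma]),
                interval_min_ma=float(row[dialect.interval_min_ma]),
                flags=flags,
            )
        except (ValueError, TypeError) as exc:
            errors.append(RowError(i, f"unparseable field: {exc}"))
            continue
        problems = rec.validate()
        if problems:
            errors.append(RowError(i, "; ".join(problems)))
        else:
            records.append(rec)
    return records, errors


def write_occurrence_table(
    records: Iterable[OccurrenceRecord],
    path: str | Path,
    dialect: Dialect | None = None,
) -> None:
    """Write records as CSV in the same dialect ``read_occurrence_table`` reads.

    Coordinates and ages use ``repr`` round-tripping, so a write→read cycle
    reproduces floats exactly.
    """
    dialect = dialect or Dialect()
    rows = []
    for r in records:
        row = {
            dialect.occurrence_id: r.occurrence_id,
            dialect.collection_id: r.collection_id,
            dialect.taxon_name: r.taxon_name,
            dialect.taxon_rank: r.taxon_rank.value,
            dialect.palaeolat: repr(r.palaeolat),
            dialect.palaeolon: repr(r.palaeolon),
            dialect.reference_id: r.reference_id,
            dialect.interval_max_ma: repr(r.interval_max_ma),
            dialect.interval_min_ma: repr(r.interval_min_ma),
        }
        for f, c in dialect.flag_columns.items():
            row[c] = "1" if f in r.flags else ""
        rows.append(row)
    cols = dialect.mandatory + [dialect.flag_columns[f] for f in sorted(KNOWN_FLAGS)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


@dataclass(frozen=True)
class FilterConfig:
    """Which cleaning filters to apply.

    Name lists identify taxa (e.g. wastebasket genera) that carry no flag in
    the input; flag filters act on the per-occurrence flag set.  Indeterminate
    occurrences are always removed.
    """

    exclude_flags: frozenset = frozenset(KNOWN_FLAGS)
    exclude_names: frozenset = frozenset()


def apply_taxon_filters(
    records: Sequence[OccurrenceRecord], config: FilterConfig | None = None
) -> tuple[list[OccurrenceRecord], dict[str, int]]:
    """Remove indeterminate, flagged and name-listed occurrences.

    Returns the retained records plus a tally of removals per category.  An
    occurrence carrying several excluded flags is tallied once per flag but
    removed once; ``tally['removed_total']`` is the true removal count.
    """
    config = config or FilterConfig()
    tally = {f"flag_{f}": 0 for f in sorted(KNOWN_FLAGS)}
    tally["indeterminate"] = 0
    tally["name_excluded"] = 0
    tally["removed_total"] = 0
    kept: list[OccurrenceRecord] = []
    for r in records:
        drop = False
        if r.taxon_rank is TaxonRank.INDETERMINATE:
            tally["indeterminate"] += 1
            drop = True
        for f in r.flags & config.exclude_flags:
            tally[f"flag_{f}"] += 1
            drop = True
        if r.taxon_name in config.exclude_names:
            tally["name_excluded"] += 1
            drop = True
        if drop:
            tally["removed_total"] += 1
        else:
            kept.append(r)
    return kept, tally


def collapse_duplicates(
    records: Sequence[OccurrenceRecord],
) -> list[OccurrenceRecord]:
    """Collapse repeated (taxon, collection) pairs to one occurrence.

    PaleoDB lists re-identifications and multiple specimens of one taxon in
    one collection as separate rows; counting methods here treat them as a
    single occurrence.  First row wins; order preserved.
    """
    seen: set[tuple[str, str]] = set()
    out = []
    for r in records:
        key = (r.taxon_name, r.collection_id)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def load_bin_scheme(path: str | Path) -> list[TimeBin]:
    """Load a bin scheme CSV with columns name,start_ma,end_ma; validates
    ordering (old to young) and non-overlap."""
    df = pd.read_csv(path)
    bins = [
        TimeBin(str(r["name"]), float(r["start_ma"]), float(r["end_ma"]))
        for _, r in df.iterrows()
    ]
    _check_scheme(bins)
    return bins


def default_bin_scheme() -> list[TimeBin]:
    """The packaged Triassic–early-Palaeogene scheme of ~9-myr bins
    (Tr1–Pg2).  Boundary ages are approximate stage groupings on the 2016
    geological timescale, not an authoritative reproduction of any published
    per-bin table."""
    with resources.files("paleospread.data").joinpath("bins_tr1_pg2.csv").open() as fh:
        df = pd.read_csv(fh)
    bins = [
        TimeBin(str(r["name"]), float(r["start_ma"]), float(r["end_ma"]))
        for _, r in df.iterrows()
    ]
    _check_scheme(bins)
    return bins


def _check_scheme(bins: Sequence[TimeBin]) -> None:
    for a, b in zip(bins, bins[1:]):
        if b.start_ma > a.end_ma:
            raise ValueError(
                f"bin scheme not ordered/non-overlapping at {a.name}->{b.name}"
            )


def assign_time_bins(
    records: Sequence[OccurrenceRecord], bins: Sequence[TimeBin]
) -> list[OccurrenceRecord]:
    """Annotate each record with the bin that entirely contains its age range.

    A record whose age interval spans a bin boundary gets ``time_bin=None``
    and is excluded from per-bin pools downstream.  Boundary-equal ages count
    as contained (closed intervals).
    """
    _check_scheme(bins)
    out = []
    for r in records:
        assigned = None
        for b in bins:
            if b.contains(r.interval_max_ma, r.interval_min_ma):
                assigned = b.name
                break
        out.append(replace(r, time_bin=assigned))
    return out


def pool_diagnostics(pool: Sequence[OccurrenceRecord]) -> PoolDiagnostics:
    """Counts plus Good's u and dominance for one pool of occurrences.

    Good's u = 1 − singletons/occurrences, a singleton being a taxon found in
    exactly one collection.  Dominance = share of the most frequent taxon.
    Ratios are ``None`` for an empty pool.
    """
    n_occ = len(pool)
    if n_occ == 0:
        return PoolDiagnostics(0, 0, 0, 0, None, None)
    taxa_counts: dict[str, int] = {}
    taxa_colls: dict[str, set[str]] = {}
    colls: set[str] = set()
    refs: set[str] = set()
    for r in pool:
        taxa_counts[r.taxon_name] = taxa_counts.get(r.taxon_name, 0) + 1
        taxa_colls.setdefault(r.taxon_name, set()).add(r.collection_id)
        colls.add(r.collection_id)
        refs.add(r.reference_id)
    singletons = sum(1 for cs in taxa_colls.values() if len(cs) == 1)
    u = min(1.0, max(0.0, 1.0 - singletons / n_occ))
    dominance = max(taxa_counts.values()) / n_occ
    return PoolDiagnostics(
        n_occurrences=n_occ,
        n_collections=len(colls),
        n_references=len(refs),
        raw_richness=len(taxa_counts),
        goods_u=u,
        dominance=dominance,
    )


def reference_threshold_filter(
    estimates: Sequence, min_refs: int = 20
) -> list[bool]:
    """Flag estimates as reportable (True) when backed by at least ``min_refs``
    references.  Estimates must expose ``n_references`` (attribute or key).
    Suppressed estimates stay in the output; this only computes the flags."""
    flags = []
    for e in estimates:
        n = e["n_references"] if isinstance(e, Mapping) else e.n_references
        flags.append(n >= min_refs)
    return flags


def write_cleaning_report(tally: Mapping[str, int], path: str | Path) -> None:
    Path(path).write_text(json.dumps(dict(tally), indent=2, sort_keys=True))
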