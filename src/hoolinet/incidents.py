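"""Per-match incident records: reading, validation, filtering, aggregation.

The unit of observation throughout the package is one football match between
a designated "head" club and an opponent, together with the number of
police-recorded hooligan incidents around that match.  Incidents are
aggregated at club level: a registry of declared fan-base alliances may name
individual *torcidas organizadas*, which are resolved to their clubs before
any statistics are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import sqrt
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Offense categories counted as aggression-based (the analysis default).
AGGRESSION_CATEGORIES = frozenset(
    {"turmoil", "threat", "slander", "assault", "battery"}
)

#: Categories present in police exports but excluded from the analysis.
NON_AGGRESSION_CATEGORIES = frozenset({"property", "drug_traffic", "other"})

ALL_CATEGORIES = AGGRESSION_CATEGORIES | NON_AGGRESSION_CATEGORIES

#: Default logical-name -> CSV column mapping.
DEFAULT_SCHEMA: Mapping[str, str] = {
    "match_id": "match_id",
    "date": "date",
    "competition": "competition",
    "head_club": "head_club",
    "opponent_club": "opponent_club",
    "incident_count": "incident_count",
    "offense_category": "offense_category",
}

REQUIRED_FIELDS = ("head_club", "opponent_club", "incident_count")


class ConfigurationError(ValueError):
    """A schema or configuration problem (missing column, bad mapping)."""


class ValidationError(ValueError):
    """One or more rows failed validation; ``errors`` lists them all."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__(
            "%d invalid row(s):\n%s" % (len(self.errors), "\n".join(self.errors))
        )


@dataclass(frozen=True)
class MatchIncidentRecord:
    """One match between a head club and an opponent, with its incident count."""

    head_club: str
    opponent_club: str
    incident_count: int
    match_id: str = ""
    date: str = ""
    competition: str = ""
    offense_category: str | None = None

    def __post_init__(self) -> None:
        if self.head_club == self.opponent_club:
            raise ValueError(
                f"head and opponent coincide: {self.head_club!r}"
            )
        if not isinstance(self.incident_count, (int, np.integer)) or isinstance(
            self.incident_count, bool
        ):
            raise ValueError(
                f"incident_count must be an integer, got {self.incident_count!r}"
            )
        if self.incident_count < 0:
            raise ValueError(
                f"incident_count must be >= 0, got {self.incident_count}"
            )


@dataclass(frozen=True)
class SummaryStats:
    """(n, mean, sd) of per-match incident counts for a pair or the benchmark.

    ``sd`` is the sample standard deviation (n-1 denominator) and is ``None``
    when ``n == 1``, where it is undefined.
    """

    n: int
    mean: float
    sd: float | None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.n == 1 and self.sd is not None:
            raise ValueError("sd is undefined (None) when n == 1")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_counts(cls, counts: Sequence[float]) -> "SummaryStats":
        arr = np.asarray(counts, dtype=float)
        if arr.size == 0:
            raise ValueError("cannot summarise an empty sample")
        n = int(arr.size)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if n > 1 else None
        return cls(n=n, mean=mean, sd=sd)


@dataclass(frozen=True)
class DeclaredAlliance:
    """A declared friend/enemy relation between a head and a partner club."""

    head: str
    partner: str
    declared_relation: str  # "friend" | "enemy"

    def __post_init__(self) -> None:
        if self.declared_relation not in ("friend", "enemy"):
            raise ValueError(
                "declared_relation must be 'friend' or 'enemy', got "
                f"{self.declared_relation!r}"
            )


# ---------------------------------------------------------------------------
# CSV I/O


def read_incident_table(
    path,
    schema_config: Mapping[str, str] | None = None,
    heads: Iterable[str] | None = None,
) -> list[MatchIncidentRecord]:
    """Read and validate an incident CSV.

    ``schema_config`` maps the logical field names (``head_club``,
    ``opponent_club``, ``incident_count``, ...) to the CSV's column names, so
    arbitrary police-export layouts can be adapted.  All malformed rows are
    collected and reported together in a single :class:`ValidationError`
    (nothing is silently dropped).
    """
    schema = dict(DEFAULT_SCHEMA)
    if schema_config:
        schema.update(schema_config)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for field_name in REQUIRED_FIELDS:
        if schema[field_name] not in df.columns:
            raise ConfigurationError(
                f"required column {schema[field_name]!r} (for {field_name}) "
                f"not found in {path}"
            )
    head_set = set(heads) if heads is not None else None
    records: list[MatchIncidentRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        rownum = idx + 2  # 1-based, after the header line
        raw_count = row[schema["incident_count"]]
        try:
            count = int(raw_count)
            if count < 0 or float(raw_count) != count:
                raise ValueError
        except (TypeError, ValueError):
            errors.append(
                f"row {rownum}: incident_count {raw_count!r} is not a "
                "non-negative integer"
            )
            continue
        head = row[schema["head_club"]]
        opponent = row[schema["opponent_club"]]
        if head_set is not None and head not in head_set:
            errors.append(f"row {rownum}: head_club {head!r} not in head set")
            continue

        def _opt(name: str) -> str:
            col = schema.get(name)
            return str(row[col]) if col in df.columns else ""

        category = _opt("offense_category") or None
        try:
            records.append(
                MatchIncidentRecord(
                    head_club=head,
                    opponent_club=opponent,
                    incident_count=count,
                    match_id=_opt("match_id"),
                    date=_opt("date"),
                    competition=_opt("competition"),
                    offense_category=category,
                )
            )
        except ValueError as exc:
            errors.append(f"row {rownum}: {exc}")
    if errors:
        raise ValidationError(errors)
    return records


def write_incident_table(records: Iterable[MatchIncidentRecord], path) -> None:
    """Write records to CSV in the default schema (round-trips losslessly)."""
    df = records_to_frame(records)
    df.to_csv(path, index=False)


def records_to_frame(records: Iterable[MatchIncidentRecord]) -> pd.DataFrame:
    rows = [
        {
            "match_id": r.match_id,
            "date": r.date,
            "competition": r.competition,
            "head_club": r.head_club,
            "opponent_club": r.opponent_club,
            "incident_count": r.incident_count,
            "offense_category": r.offense_category or "",
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "match_id",
            "date",
            "competition",
            "head_club",
            "opponent_club",
            "incident_count",
            "offense_category",
        ],
    )


def read_registry(path) -> list[DeclaredAlliance]:
    """Read a declared-alliance registry CSV (head, partner, declared_relation)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("head", "partner", "declared_relation"):
        if col not in df.columns:
            raise ConfigurationError(f"registry missing column {col!r}")
    entries = [
        DeclaredAlliance(row["head"], row["partner"], row["declared_relation"])
        for _, row in df.iterrows()
    ]
    _check_registry_consistency(entries)
    return entries


def write_registry(registry: Iterable[DeclaredAlliance], path) -> None:
    pd.DataFrame(
        [
            {"head": e.head, "partner": e.partner,
             "declared_relation": e.declared_relation}
            for e in registry
        ]
    ).to_csv(path, index=False)


def _check_registry_consistency(registry: Sequence[DeclaredAlliance]) -> None:
    seen: dict[tuple[str, str], str] = {}
    for e in registry:
        key = (e.head, e.partner)
        if key in seen and seen[key] != e.declared_relation:
            raise ValidationError(
                [f"contradictory declarations for {key}: "
                 f"{seen[key]} vs {e.declared_relation}"]
            )
        seen[key] = e.declared_relation


# ---------------------------------------------------------------------------
# Filtering and aggregation


def filter_aggression_offenses(
    records: Iterable[MatchIncidentRecord],
    allowed_categories: Iterable[str] = AGGRESSION_CATEGORIES,
    strict: bool = False,
) -> list[MatchIncidentRecord]:
    """Keep only records whose offense category is in ``allowed_categories``.

    Records lacking a category pass through with a logged warning, unless
    ``strict`` is set, in which case they are rejected.  An empty result is a
    warning, not an error: some scopes genuinely contain no aggression data.
    """
    allowed = set(allowed_categories)
    if not allowed:
        raise ValueError("allowed_categories must be non-empty")
    kept: list[MatchIncidentRecord] = []
    n_uncategorised = 0
    for r in records:
        if r.offense_category is None:
            n_uncategorised += 1
            if not strict:
                kept.append(r)
        elif r.offense_category in allowed:
            kept.append(r)
    if n_uncategorised:
        verb = "rejected" if strict else "passed through"
        logger.warning(
            "%d record(s) without an offense category were %s",
            n_uncategorised, verb,
        )
    if not kept:
        logger.warning("offense filter produced an empty record set")
    return kept


def pair_counts(
    records: Iterable[MatchIncidentRecord], club_a: str, club_b: str
) -> np.ndarray:
    """Per-match incident counts for matches between ``club_a`` and ``club_b``."""
    pair = {club_a, club_b}
    return np.array(
        [r.incident_count for r in records
         if {r.head_club, r.opponent_club} == pair],
        dtype=float,
    )


def aggregate_pair_stats(
    records: Iterable[MatchIncidentRecord], club_a: str, club_b: str
) -> SummaryStats | None:
    """Summary statistics for one club pair.

    Returns ``None`` when the pair has no matches at all — a state distinct
    from "matches with zero incidents", which yields mean 0 and sd 0.
    """
    counts = pair_counts(records, club_a, club_b)
    if counts.size == 0:
        return None
    return SummaryStats.from_counts(counts)


def pooled_benchmark(
    records: Iterable[MatchIncidentRecord],
    scope_clubs: Iterable[str] | None = None,
    exclude_pair: tuple[str, str] | None = None,
) -> SummaryStats:
    """Benchmark statistics over all per-match counts in the configured scope.

    The benchmark is the pooled per-match incident distribution across all
    club pairs, including the heads.  ``scope_clubs`` restricts the pool to
    matches where both clubs belong to the named subset; ``exclude_pair``
    drops one pair's matches (a leave-one-pair-out benchmark, used by the
    calibration machinery to remove the tested pair's own contamination).
    """
    scope = set(scope_clubs) if scope_clubs is not None else None
    excl = frozenset(exclude_pair) if exclude_pair is not None else None
    counts = [
        r.incident_count
        for r in records
        if (scope is None or {r.head_club, r.opponent_club} <= scope)
        and (excl is None or {r.head_club, r.opponent_club} != excl)
    ]
    if not counts:
        raise ValueError("benchmark scope contains no matches")
    return SummaryStats.from_counts(counts)


def standard_error_of_mean(stats: SummaryStats) -> float:
    """SEM = sd / sqrt(n) of a summary-statistics group."""
    if stats.sd is None:
        raise ValueError("SEM undefined for n == 1")
    return stats.sd / sqrt(stats.n)
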