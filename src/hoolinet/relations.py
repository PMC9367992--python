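"""Benchmark-referenced unequal-variance tests and relation classification.

The two-step procedure works entirely from summary statistics.  Step one
compares a head pair's per-match incident mean with the pooled benchmark
mean using an unequal-variance (Welch) t statistic,

    U(a,b) = (mean(a,b) - mean_bench) / sqrt(sd(a,b)^2/n(a,b) + sd_bench^2/n_bench),

and labels the pair a *rivalry* (mean above benchmark, null rejected), an
*alliance* (mean below benchmark, null rejected) or *undefined*.  Step two
applies the same test to each (head, third-club) pair; the pair of component
outcomes, together with the head-pair relation, classifies the triple as a
coup, peer, clash or split affinity.  Declared friend/enemy registries give
the transitive-logic expectation each observed affinity is checked against.

Significance uses a two-tier convention: strong below ``alpha_strong``
(default 0.05) and weak between ``alpha_strong`` and ``alpha_weak``
(default 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .incidents import (
    DeclaredAlliance,
    MatchIncidentRecord,
    SummaryStats,
    ValidationError,
    aggregate_pair_stats,
    pooled_benchmark,
)

Sidedness = Literal["one_tailed_directional", "two_tailed"]
DfRule = Literal["welch_satterthwaite", "additive"]

RIVALRY = "rivalry"
ALLIANCE = "alliance"
UNDEFINED = "undefined"

COUP = "coup"
PEER = "peer"
CLASH = "clash"
SPLIT = "split"

FRIEND = "friend"
ENEMY = "enemy"


@dataclass(frozen=True)
class WelchTestResult:
    statistic: float | None
    df: float | None
    p_value: float | None


@dataclass(frozen=True)
class UnderlyingRelation:
    """Outcome of the step-one test for one pair against the benchmark."""

    head_a: str
    head_b: str
    statistic: float | None
    df: float | None
    p_value: float | None
    label: str  # rivalry | alliance | undefined
    tier: str  # strong | weak | none
    n: int | None = None
    mean: float | None = None
    sd: float | None = None

    @property
    def defined(self) -> bool:
        return self.label != UNDEFINED


@dataclass(frozen=True)
class AffinityRelation:
    """Step-two classification of a (head_a, head_b, club_k) triple."""

    head_a: str
    head_b: str
    club_k: str
    head_relation: UnderlyingRelation
    component_a: UnderlyingRelation
    component_b: UnderlyingRelation
    affinity_class: str  # coup | peer | clash | split | undefined


@dataclass(frozen=True)
class AssumedRelation:
    """A user-supplied head-pair relation override, logged as assumed.

    Covers the case where the inferred relation is undefined but an analysis
    (e.g. a coup extraction) needs a definite friendship, on circumstantial
    grounds the analyst takes responsibility for.
    """

    head_a: str
    head_b: str
    relation: str  # friend | enemy
    provenance: str = "assumed"

    def __post_init__(self) -> None:
        if self.relation not in (FRIEND, ENEMY):
            raise ValueError(f"relation must be friend|enemy, got {self.relation!r}")


@dataclass(frozen=True)
class BedouinVerdict:
    """Concordance of one (head, declared partner) interaction with the
    transitive friend/enemy expectation."""

    head: str
    partner: str
    expected_relation: str | None  # friend | enemy | None (underivable)
    observed: UnderlyingRelation | None  # None when the pair has no matches
    verdict: str  # supports | contradicts | inconclusive


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the two-step procedure."""

    alpha_strong: float = 0.05
    alpha_weak: float = 0.1
    sidedness: Sidedness = "one_tailed_directional"
    df_rule: DfRule = "welch_satterthwaite"
    benchmark: SummaryStats | None = None  # None -> pooled from the records
    benchmark_scope: tuple[str, ...] | None = None
    assumed_relations: tuple[AssumedRelation, ...] = ()
    holm: bool = False  # report Holm-adjusted p-values as an extra column

    def __post_init__(self) -> None:
        if not (0 < self.alpha_strong < self.alpha_weak <= 1):
            raise ValueError("need 0 < alpha_strong < alpha_weak <= 1")


# ---------------------------------------------------------------------------
# The test itself


def welch_test(
    sample: SummaryStats,
    benchmark: SummaryStats,
    sidedness: Sidedness = "one_tailed_directional",
    df_rule: DfRule = "welch_satterthwaite",
) -> WelchTestResult:
    """Unequal-variance t test of a pair sample against the benchmark group.

    The one-tailed directional p-value is the tail probability in the
    direction of the observed mean difference (the convention under which the
    published incident tables reproduce).  ``df_rule`` selects between the
    Welch–Satterthwaite fractional approximation (default) and the additive
    rule (n1 - 1) + (n2 - 1).

    The p-value is undefined (``None``) for degenerate samples: fewer than
    two matches, or a zero-variance sample (incident tables print these rows
    with a dash).
    """
    if benchmark.n < 2 or benchmark.sd is None:
        raise ValueError("benchmark must have n >= 2 and a defined sd")
    if sample.n < 2 or sample.sd is None or sample.sd == 0:
        return WelchTestResult(None, None, None)
    se2_s = sample.sd**2 / sample.n
    se2_b = benchmark.sd**2 / benchmark.n
    if se2_s + se2_b == 0:
        # both groups constant: no variability to test against
        return WelchTestResult(None, None, None)
    statistic = (sample.mean - benchmark.mean) / np.sqrt(se2_s + se2_b)
    if df_rule == "welch_satterthwaite":
        df = (se2_s + se2_b) ** 2 / (
            se2_s**2 / (sample.n - 1) + se2_b**2 / (benchmark.n - 1)
        )
    elif df_rule == "additive":
        df = float((sample.n - 1) + (benchmark.n - 1))
    else:
        raise ValueError(f"unknown df rule {df_rule!r}")
    tail = float(sps.t.sf(abs(statistic), df))
    if sidedness == "one_tailed_directional":
        p = tail if statistic != 0 else 0.5
    elif sidedness == "two_tailed":
        p = min(1.0, 2.0 * tail)
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return WelchTestResult(float(statistic), float(df), p)


def label_from_test(
    p_value: float | None,
    direction: int,
    alpha_strong: float = 0.05,
    alpha_weak: float = 0.1,
) -> tuple[str, str]:
    """Map a p-value and a mean-difference direction to (label, tier).

    ``direction`` is the sign of (pair mean - benchmark mean): positive means
    the rivalry side, negative the alliance side.  Below ``alpha_strong`` the
    tier is strong; between the alphas, weak; otherwise the relation is
    undefined.
    """
    if p_value is None or p_value >= alpha_weak or direction == 0:
        return UNDEFINED, "none"
    tier = "strong" if p_value < alpha_strong else "weak"
    return (RIVALRY if direction > 0 else ALLIANCE), tier


def classify_underlying(
    pair: SummaryStats,
    benchmark: SummaryStats,
    alpha_strong: float = 0.05,
    alpha_weak: float = 0.1,
    sidedness: Sidedness = "one_tailed_directional",
    df_rule: DfRule = "welch_satterthwaite",
    club_a: str = "",
    club_b: str = "",
) -> UnderlyingRelation:
    """Step-one classification of one pair against the benchmark."""
    result = welch_test(pair, benchmark, sidedness=sidedness, df_rule=df_rule)
    direction = int(np.sign(pair.mean - benchmark.mean))
    label, tier = label_from_test(result.p_value, direction, alpha_strong, alpha_weak)
    return UnderlyingRelation(
        head_a=club_a,
        head_b=club_b,
        statistic=result.statistic,
        df=result.df,
        p_value=result.p_value,
        label=label,
        tier=tier,
        n=pair.n,
        mean=pair.mean,
        sd=pair.sd,
    )


# ---------------------------------------------------------------------------
# Affinity taxonomy

#: (head-pair label, component-a label, component-b label) -> affinity class.
#: Friends sharing an enemy stage a coup; friends of a mutual friend are
#: peers; enemies with a mutual enemy clash; enemies sharing a friend split.
_AFFINITY_TABLE: Mapping[tuple[str, str, str], str] = {
    (ALLIANCE, RIVALRY, RIVALRY): COUP,
    (ALLIANCE, ALLIANCE, ALLIANCE): PEER,
    (RIVALRY, RIVALRY, RIVALRY): CLASH,
    (RIVALRY, ALLIANCE, ALLIANCE): SPLIT,
}


def classify_affinity(
    head_relation: UnderlyingRelation,
    component_a: UnderlyingRelation,
    component_b: UnderlyingRelation,
) -> AffinityRelation:
    """Classify a (head_a, head_b, club_k) triple from its three relations.

    Any combination outside the four canonical patterns (including any
    undefined input) yields the ``undefined`` class, which is a valid
    outcome, not an error.
    """
    key = (head_relation.label, component_a.label, component_b.label)
    affinity = _AFFINITY_TABLE.get(key, UNDEFINED)
    return AffinityRelation(
        head_a=head_relation.head_a,
        head_b=head_relation.head_b,
        club_k=component_a.head_b or component_b.head_b,
        head_relation=head_relation,
        component_a=component_a,
        component_b=component_b,
        affinity_class=affinity,
    )


# ---------------------------------------------------------------------------
# Declared registry: expectations under transitive friend/enemy logic


def _compose(r1: str, r2: str) -> str:
    """Transitive friend/enemy composition (friend of enemy = enemy, ...)."""
    return FRIEND if r1 == r2 else ENEMY


def declared_relation(
    registry: Sequence[DeclaredAlliance],
    a: str,
    b: str,
    assumed: Sequence[AssumedRelation] = (),
) -> str | None:
    """Direct declared (or assumed) relation between two clubs, if any.

    Assumed overrides take precedence over declarations, mirroring an
    analyst's explicit circumstantial call.
    """
    for o in assumed:
        if {o.head_a, o.head_b} == {a, b}:
            return o.relation
    found = None
    for e in registry:
        if {e.head, e.partner} == {a, b}:
            if found is not None and found != e.declared_relation:
                raise ValidationError(
                    [f"contradictory declarations for ({a}, {b})"]
                )
            found = e.declared_relation
    return found


def expected_relation(
    registry: Sequence[DeclaredAlliance],
    club: str,
    other: str,
    heads: Sequence[str] = (),
    assumed: Sequence[AssumedRelation] = (),
) -> str | None:
    """Expected friend/enemy relation between two clubs under transitive logic.

    A direct declaration wins.  Otherwise every one-hop path through a head
    ``h`` with both links declared composes (friend of my enemy is my enemy,
    etc.); agreeing paths give the expectation, conflicting paths or no path
    give ``None`` (inconclusive).
    """
    direct = declared_relation(registry, club, other, assumed)
    if direct is not None:
        return direct
    derived: set[str] = set()
    for h in heads:
        if h in (club, other):
            continue
        r1 = declared_relation(registry, club, h, assumed)
        r2 = declared_relation(registry, h, other, assumed)
        if r1 is not None and r2 is not None:
            derived.add(_compose(r1, r2))
    if len(derived) == 1:
        return derived.pop()
    return None


#: (head-pair declared, k vs a declared, k vs b declared) -> expected class.
_EXPECTED_AFFINITY: Mapping[tuple[str, str, str], str] = {
    (FRIEND, ENEMY, ENEMY): COUP,
    (FRIEND, FRIEND, FRIEND): PEER,
    (ENEMY, ENEMY, ENEMY): CLASH,
    (ENEMY, FRIEND, FRIEND): SPLIT,
}


def expected_affinity_from_declarations(
    registry: Sequence[DeclaredAlliance],
    triple: tuple[str, str, str],
    heads: Sequence[str] = (),
    assumed: Sequence[AssumedRelation] = (),
) -> str | None:
    """Expected coup/peer/clash/split class of a (a, b, k) triple.

    Missing links are filled in by transitive composition where possible;
    an underivable or internally inconsistent triple returns ``None``
    (inconclusive).
    """
    a, b, k = triple
    hs = list(heads) or [a, b]
    r_ab = declared_relation(registry, a, b, assumed)
    r_ak = expected_relation(registry, k, a, hs, assumed)
    r_bk = expected_relation(registry, k, b, hs, assumed)
    if r_ab is None or r_ak is None or r_bk is None:
        return None
    return _EXPECTED_AFFINITY.get((r_ab, r_ak, r_bk))


# ---------------------------------------------------------------------------
# The full second step


@dataclass
class BedouinTestResult:
    verdicts: list[BedouinVerdict]
    table: pd.DataFrame
    benchmark: SummaryStats
    counts: dict[str, int]  # verdict -> number of interactions
    clubs_supported: list[str]
    clubs_without_support: list[str]


def _observed_matches_expected(expected: str, label: str) -> bool:
    return (expected == FRIEND and label == ALLIANCE) or (
        expected == ENEMY and label == RIVALRY
    )


def evaluate_bedouin_hypothesis(
    records: Sequence[MatchIncidentRecord],
    registry: Sequence[DeclaredAlliance],
    heads: Sequence[str],
    config: AnalysisConfig = AnalysisConfig(),
) -> BedouinTestResult:
    """Run the full second step: one verdict per (head, declared partner).

    For every head and every non-head club named in the registry, the
    expected friend/enemy relation is derived from the declarations (direct,
    or composed through another head), the observed relation is classified
    against the benchmark, and the two are compared.  An interaction with no
    match data, a zero-variance sample, or an underivable expectation is
    inconclusive.
    """
    if not heads:
        raise ValueError("heads must be non-empty")
    head_set = set(heads)
    partners = sorted(
        {e.partner for e in registry if e.partner not in head_set}
        | {e.head for e in registry if e.head not in head_set}
    )
    benchmark = config.benchmark
    if benchmark is None:
        benchmark = pooled_benchmark(records, scope_clubs=config.benchmark_scope)

    verdicts: list[BedouinVerdict] = []
    rows: list[dict] = []
    for head in heads:
        for club in partners:
            expected = expected_relation(
                registry, club, head, heads, config.assumed_relations
            )
            pair = aggregate_pair_stats(records, head, club)
            observed = None
            if pair is not None:
                observed = classify_underlying(
                    pair,
                    benchmark,
                    alpha_strong=config.alpha_strong,
                    alpha_weak=config.alpha_weak,
                    sidedness=config.sidedness,
                    df_rule=config.df_rule,
                    club_a=head,
                    club_b=club,
                )
            if pair is None and expected is None:
                continue  # nothing ties this (head, club) pair together
            if observed is None or not observed.defined or expected is None:
                verdict = "inconclusive"
            elif _observed_matches_expected(expected, observed.label):
                verdict = "supports"
            else:
                verdict = "contradicts"
            verdicts.append(
                BedouinVerdict(
                    head=head,
                    partner=club,
                    expected_relation=expected,
                    observed=observed,
                    verdict=verdict,
                )
            )
            rows.append(
                {
                    "head": head,
                    "partner": club,
                    "n": pair.n if pair else 0,
                    "mean": pair.mean if pair else np.nan,
                    "sd": (pair.sd if pair and pair.sd is not None else np.nan),
                    "statistic": (
                        observed.statistic
                        if observed and observed.statistic is not None
                        else np.nan
                    ),
                    "df": observed.df if observed and observed.df is not None else np.nan,
                    "p_value": (
                        observed.p_value
                        if observed and observed.p_value is not None
                        else np.nan
                    ),
                    "label": observed.label if observed else "no_data",
                    "tier": observed.tier if observed else "none",
                    "expected": expected or "inconclusive",
                    "verdict": verdict,
                }
            )
    table = pd.DataFrame(rows)
    if config.holm and len(table) and table["p_value"].notna().any():
        table["p_holm"] = _holm_adjust(table["p_value"].to_numpy())
    counts = {v: 0 for v in ("supports", "contradicts", "inconclusive")}
    for v in verdicts:
        counts[v.verdict] += 1
    supported = sorted({v.partner for v in verdicts if v.verdict == "supports"})
    without = sorted(set(partners) - set(supported))
    return BedouinTestResult(
        verdicts=verdicts,
        table=table,
        benchmark=benchmark,
        counts=counts,
        clubs_supported=supported,
        clubs_without_support=without,
    )


def _holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (NaNs passed through)."""
    from statsmodels.stats.multitest import multipletests

    out = np.full_like(p, np.nan, dtype=float)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="holm")[1]
    return out


def classify_all_pairs(
    records: Sequence[MatchIncidentRecord],
    heads: Sequence[str],
    benchmark: SummaryStats | None = None,
    config: AnalysisConfig = AnalysisConfig(),
) -> dict[tuple[str, str], UnderlyingRelation]:
    """Step-one classification of every (head, club) pair with match data."""
    if benchmark is None:
        benchmark = config.benchmark or pooled_benchmark(
            records, scope_clubs=config.benchmark_scope
        )
    pairs: dict[tuple[str, str], UnderlyingRelation] = {}
    head_set = set(heads)
    seen: set[frozenset] = set()
    for r in records:
        for head in head_set & {r.head_club, r.opponent_club}:
            other = (
                r.opponent_club if head == r.head_club else r.head_club
            )
            key = frozenset((head, other))
            if key in seen:
                continue
            seen.add(key)
            stats = aggregate_pair_stats(records, head, other)
            assert stats is not None
            rel = classify_underlying(
                stats,
                benchmark,
                alpha_strong=config.alpha_strong,
                alpha_weak=config.alpha_weak,
                sidedness=config.sidedness,
                df_rule=config.df_rule,
                club_a=head,
                club_b=other,
            )
            pairs[(head, other)] = rel
            if other in head_set:
                pairs[(other, head)] = replace(rel, head_a=other, head_b=head)
    return pairs
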