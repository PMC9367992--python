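"""Deterministic fixture assembled from the published summary tables.

The original per-match police dataset is unpublished.  What the source
article prints is, for each tested (head, partner fan base) interaction, the
per-match incident mean and sample SD, plus the pooled benchmark group
(n = 330, mean 2.28181800, SD 3.91970700).  Because counts are small
integers, the reconstruction oracle recovers a minimal integer count vector
for every row, so the entire second step can be re-run end to end from the
printed numbers alone.

The declared-alliance registry here is synthetic: the article's appendix
registry is not reproduced in the available text, so this one is
constructed to be consistent with every narrative statement of the results
section (which fan bases were declared friends of which side, which
interactions supported or contradicted the transitive friend/enemy logic).

Head-pair ("step one") relations are carried as printed labels: their
benchmark group is underdetermined in the source, so their p-values are not
recomputed here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .incidents import DeclaredAlliance, MatchIncidentRecord, SummaryStats
from .reconstruct import reconstruct_counts
from .relations import AssumedRelation, UnderlyingRelation, label_from_test

SPORT = "Sport Recife"
SANTA = "Santa Cruz"
NAUTICO = "Nautico"
HEADS = (SPORT, SANTA, NAUTICO)

#: Published benchmark ("first group") statistics.
BENCHMARK = SummaryStats(n=330, mean=2.28181800, sd=3.91970700)

# One entry per published second-step row:
# (head, partner club, fan base, printed mean, printed SD, printed p or None,
#  mean kwargs for the reconstruction oracle)
TABLE_ROWS = [
    (SPORT, "Vasco", "Forca Jovem e Mancha Negra", 6, 4.358899, 0.13857,
     dict(mean_mode="exact")),
    (SPORT, "Atletico-MG", "Galoucura", 1.66, 2.73252, 0.30494,
     dict(mean_digits=2, mean_mode="trunc", sd_digits=5)),
    (SPORT, "Bahia", "Bamor", 1.5, 0.707107, 0.16674, dict(mean_mode="exact")),
    (SPORT, "Ypiranga", "Furia Jovem do Ypiranga", 0.5, 0.707107, 0.06417,
     dict(mean_mode="exact")),
    (SPORT, "America-RN", "Mafia Vermelha", 2.5, 2.12132, 0.45412,
     dict(mean_mode="exact", sd_digits=5)),
    (SPORT, "Palmeiras", "TUP", 0.833, 0.752773, 0.00131, dict(mean_digits=3)),
    (SPORT, "Botafogo", "Torcida Jovem (Botafogo)", 6.33, 6.110101, 0.18477,
     dict(mean_digits=2)),
    (SPORT, "Gremio", "Geral", 2, 2, 0.41571, dict(mean_mode="exact", sd_digits=6)),
    (SPORT, "Ceara", "Cearamor", 1.5, 2.12132, 0.34699,
     dict(mean_mode="exact", sd_digits=5)),
    (SANTA, "Cruzeiro", "Mafia Azul", 0, 0, None, dict(mean_mode="exact")),
    (SANTA, "Sao Paulo", "Independente e Dragoes da Real", 0, 0, None,
     dict(mean_mode="exact")),
    (SANTA, "Flamengo", "Jovem Fla", 0, 0, None, dict(mean_mode="exact")),
    (SANTA, "Internacional", "Camisa 12", 6, 1.414214, 0.076807,
     dict(mean_mode="exact")),
    (SANTA, "Remo", "Remocada", 4, 2.82843, 0.257332,
     dict(mean_mode="exact", sd_digits=5)),
    (SANTA, "Brasiliense", "Faccao Brasiliense", 5.5, 3.535534, 0.123865,
     dict(mean_mode="exact")),
    (SANTA, "Palmeiras", "TUP", 0, 0, None, dict(mean_mode="exact")),
    (SANTA, "Botafogo", "Torcida Jovem (Botafogo)", 4, 5.656854, 0.37086,
     dict(mean_mode="exact")),
    (SANTA, "Gremio", "Geral", 2, 2.828427, 0.45549, dict(mean_mode="exact")),
    (SANTA, "Ceara", "Cearamor", 1, 1.414214, 0.2074, dict(mean_mode="exact")),
    (NAUTICO, "Cruzeiro", "Mafia Azul", 0.5, 0.707107, 0.06417,
     dict(mean_mode="exact")),
    (NAUTICO, "Sao Paulo", "Independente e Dragoes da Real", 3.5, 4.949747,
     0.3934, dict(mean_mode="exact")),
    (NAUTICO, "Flamengo", "Jovem Fla", 3, 2.645751, 0.34287,
     dict(mean_mode="exact")),
    (NAUTICO, "Internacional", "Camisa 12", 2.75, 2.06155, 0.34222,
     dict(mean_mode="exact", sd_digits=5)),
    (NAUTICO, "Remo", "Remocada", 0, 0, None, dict(mean_mode="exact")),
    (NAUTICO, "Brasiliense", "Faccao Brasiliense", 0, 0, None,
     dict(mean_mode="exact")),
    (NAUTICO, "Vasco", "Forca Jovem e Mancha Negra", 1, 1.414214, 0.2074,
     dict(mean_mode="exact")),
    (NAUTICO, "Atletico-MG", "Galoucura", 1, 0.707107, 0.00458,
     dict(mean_mode="exact")),
    (NAUTICO, "Bahia", "Bamor", 1, 1.414214, 0.2074, dict(mean_mode="exact")),
    (NAUTICO, "Ypiranga", "Furia Jovem do Ypiranga", 1.75, 1.258306, 0.23578,
     dict(mean_mode="exact")),
    (NAUTICO, "America-RN", "Mafia Vermelha", 2.5, 2.12132, 0.45412,
     dict(mean_mode="exact", sd_digits=5)),
]

# Published step-one rows: (head_a, head_b, mean, sd, p, label).
HEAD_RELATION_ROWS = [
    (SPORT, SANTA, 14.96, 24.32, 0.018, "rivalry"),
    (SPORT, NAUTICO, 6.027, 8.036, 0.048, "rivalry"),
    (SANTA, NAUTICO, 3.714, 4.817, 0.477, "undefined"),
]

#: The analyst override used for the coup instance: the two non-focal heads
#: treated as mutual friends on circumstantial grounds.
ASSUMED_SANTA_NAUTICO_FRIENDS = AssumedRelation(SANTA, NAUTICO, "friend")


def build_registry() -> list[DeclaredAlliance]:
    """Synthetic declared-alliance registry consistent with the published
    results narrative.

    Heads declare mutual rivalry.  Each partner club is a declared friend of
    exactly one head, chosen so the transitive friend/enemy expectations
    reproduce the published reading: the three "contrary alliance" partners
    (Ypiranga, Palmeiras, Cruzeiro) sit on the enemies' side of the head
    they showed an alliance with, Internacional is expected hostile to
    Santa Cruz, and Atletico-MG is a friend of Santa Cruz (hence expected
    friendly to Nautico once the assumed alliance override is in force).
    """
    reg = [
        DeclaredAlliance(SPORT, SANTA, "enemy"),
        DeclaredAlliance(SPORT, NAUTICO, "enemy"),
        DeclaredAlliance(SANTA, NAUTICO, "enemy"),
    ]
    friends_of_santa = [
        "Vasco", "Atletico-MG", "Bahia", "Ypiranga", "America-RN",
        "Palmeiras", "Botafogo", "Gremio", "Ceara",
    ]
    friends_of_sport = [
        "Cruzeiro", "Sao Paulo", "Flamengo", "Internacional", "Remo",
        "Brasiliense",
    ]
    reg.extend(DeclaredAlliance(SANTA, c, "friend") for c in friends_of_santa)
    reg.extend(DeclaredAlliance(SPORT, c, "friend") for c in friends_of_sport)
    return reg


@dataclass
class PaperFixture:
    records: list[MatchIncidentRecord]
    registry: list[DeclaredAlliance]
    benchmark: SummaryStats
    heads: tuple[str, ...]
    head_relations: dict[tuple[str, str], UnderlyingRelation]
    assumed_relations: tuple[AssumedRelation, ...]
    printed_p: dict[tuple[str, str], float | None]  # (head, partner) -> p


def build_paper_fixture() -> PaperFixture:
    """Assemble the deterministic fixture from the printed tables.

    Every second-step row is turned into per-match records via the
    reconstruction oracle (raising if any row fails to reconstruct, which
    would indicate a regression in the oracle).  Identical across runs: no
    randomness is involved.
    """
    records: list[MatchIncidentRecord] = []
    printed_p: dict[tuple[str, str], float | None] = {}
    match_no = 0
    for head, club, fan_base, mean, sd, p, mean_kwargs in TABLE_ROWS:
        res = reconstruct_counts(mean, sd, **mean_kwargs)
        if not res.found:
            raise RuntimeError(
                f"row ({head}, {club}) failed to reconstruct from "
                f"mean={mean}, sd={sd}"
            )
        printed_p[(head, club)] = p
        for c in res.counts:
            match_no += 1
            records.append(
                MatchIncidentRecord(
                    head_club=head,
                    opponent_club=club,
                    incident_count=c,
                    match_id=f"t4_{match_no:03d}",
                    competition="reconstructed",
                )
            )
    head_relations = {}
    for a, b, mean, sd, p, label in HEAD_RELATION_ROWS:
        direction = {"rivalry": 1, "alliance": -1, "undefined": 0}[label]
        lab, tier = label_from_test(p, direction)
        head_relations[(a, b)] = UnderlyingRelation(
            head_a=a, head_b=b, statistic=None, df=None, p_value=p,
            label=lab, tier=tier, n=None, mean=mean, sd=sd,
        )
    return PaperFixture(
        records=records,
        registry=build_registry(),
        benchmark=BENCHMARK,
        heads=HEADS,
        head_relations=head_relations,
        assumed_relations=(ASSUMED_SANTA_NAUTICO_FRIENDS,),
        printed_p=printed_p,
    )
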