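"""Published occurrence counts for alopecia prescription corpora.

A published survey of the alopecia-treatment literature reports, for 312
internal-route herbal prescriptions over 258 herbs, the occurrence counts of
the most frequent herbs and the co-occurrence counts of the strongest two-
and three-herb combinations. The raw transaction data were never deposited,
but those printed counts fully determine the support / confidence / lift of
the corresponding association rules, so fixture corpora realizing them let
the mining stage be checked against the published values.

Counts are keyed by genus-level short ids; ``LATIN_NAMES`` maps them to the
full botanical names.
"""

from __future__ import annotations

from .corpus import Corpus, CountSpec, build_fixture_corpus

#: Total prescriptions by route in the surveyed corpus.
N_TOTAL = 489
N_INTERNAL = 312
N_EXTERNAL = 177

#: Distinct herbs appearing in internal prescriptions.
N_HERBS_INTERNAL = 258

LATIN_NAMES: dict[str, str] = {
    "Angelica": "Angelica sinensis (Oliv.) Diels",
    "Ligusticum": "Ligusticum chuanxiong Hort.",
    "Polygonum": "Polygonum multiflorum Thunb.",
    "Rehmannia_prep": "Rehmannia glutinosa Libosch. (prepared)",
    "Poria": "Poria cocos (Schw.) Wolf",
    "Ligustrum": "Ligustrum lucidum Ait.",
    "Rehmannia_raw": "Rehmannia glutinosa Libosch.",
    "Glycyrrhiza": "Glycyrrhiza uralensis Fisch.",
    "Eclipta": "Eclipta prostrata L.",
    "Lycium": "Lycium barbarum L.",
}

#: Occurrence counts of the ten most frequent herbs in the 312 internal
#: prescriptions.
INTERNAL_MARGINALS: dict[str, int] = {
    "Angelica": 171,
    "Ligusticum": 132,
    "Polygonum": 175,
    "Rehmannia_prep": 137,
    "Poria": 103,
    "Ligustrum": 96,
    "Rehmannia_raw": 95,
    "Glycyrrhiza": 90,
    "Eclipta": 89,
    "Lycium": 88,
}

#: Co-occurrence counts of the top ten herb pairs (internal prescriptions).
PAIR_COUNTS: dict[frozenset[str], int] = {
    frozenset({"Polygonum", "Angelica"}): 120,
    frozenset({"Ligusticum", "Angelica"}): 107,
    frozenset({"Rehmannia_prep", "Angelica"}): 95,
    frozenset({"Rehmannia_prep", "Polygonum"}): 87,
    frozenset({"Ligusticum", "Polygonum"}): 82,
    frozenset({"Ligusticum", "Rehmannia_prep"}): 79,
    frozenset({"Ligustrum", "Polygonum"}): 72,
    frozenset({"Lycium", "Polygonum"}): 69,
    frozenset({"Ligustrum", "Eclipta"}): 69,
    frozenset({"Eclipta", "Polygonum"}): 67,
}

#: Co-occurrence counts of published herb triples whose three member pairs
#: all have published counts (only those are realizable as fixtures).
TRIPLE_COUNTS: dict[frozenset[str], int] = {
    frozenset({"Ligusticum", "Polygonum", "Angelica"}): 73,
    frozenset({"Rehmannia_prep", "Polygonum", "Angelica"}): 67,
    frozenset({"Rehmannia_prep", "Ligusticum", "Angelica"}): 66,
    frozenset({"Eclipta", "Polygonum", "Ligustrum"}): 52,
    frozenset({"Ligusticum", "Polygonum", "Rehmannia_prep"}): 47,
}


def pair_fixture(pair: frozenset[str] | set[str]) -> Corpus:
    """Fixture corpus realizing one published pair's counts (N=312)."""
    pair = frozenset(pair)
    spec = CountSpec(
        n=N_INTERNAL,
        marginals={h: INTERNAL_MARGINALS[h] for h in pair},
        joints={pair: PAIR_COUNTS[pair]},
    )
    return build_fixture_corpus(spec)


def triple_fixture(triple: frozenset[str] | set[str]) -> Corpus:
    """Fixture corpus realizing one published triple and its member pairs."""
    triple = frozenset(triple)
    joints: dict[frozenset[str], int] = {triple: TRIPLE_COUNTS[triple]}
    for a in triple:
        for b in triple:
            if a < b:
                joints[frozenset({a, b})] = PAIR_COUNTS[frozenset({a, b})]
    spec = CountSpec(
        n=N_INTERNAL,
        marginals={h: INTERNAL_MARGINALS[h] for h in triple},
        joints=joints,
    )
    return build_fixture_corpus(spec)
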