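"""Apriori itemset counting and association-rule scoring.

Herbs are items, prescriptions are transactions. An association rule
X -> Y (X, Y disjoint herb sets) is scored by

* support    = count(X ∪ Y) / N
* confidence = count(X ∪ Y) / count(X)
* lift       = confidence / (count(Y) / N)

Counting is level-wise apriori: size-k candidates are joined from frequent
(k-1)-itemsets and pruned by anti-monotonicity (a superset can never be more
frequent than any subset) before transactions are scanned.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import pandas as pd

from .corpus import Corpus


class MiningError(ValueError):
    """Raised on invalid mining parameters or undefined metrics."""


@dataclass(frozen=True)
class AssociationRule:
    """A scored rule antecedent -> consequent over herb itemsets."""

    antecedent: tuple[str, ...]
    consequent: tuple[str, ...]
    support: float
    confidence: float
    lift: float
    frequency: int

    @property
    def itemset(self) -> tuple[str, ...]:
        return tuple(sorted(self.antecedent + self.consequent))


def count_itemsets(corpus: Corpus, max_len: int = 3,
                   min_count: int = 1) -> dict[frozenset[str], int]:
    """Exact transaction counts for every itemset of size <= ``max_len``.

    Returns every itemset occurring in at least ``min_count`` transactions.
    Candidate generation is level-wise with apriori pruning; the result does
    not depend on transaction order.
    """
    if max_len not in (1, 2, 3):
        raise MiningError(f"max_len must be 1, 2 or 3, got {max_len}")
    if corpus.n == 0:
        raise MiningError("cannot mine an empty corpus")
    if min_count < 1:
        raise MiningError("min_count must be >= 1")

    transactions = corpus.transactions()
    counts: dict[frozenset[str], int] = {}

    # level 1
    level: dict[frozenset[str], int] = {}
    for t in transactions:
        for h in t:
            s = frozenset({h})
            level[s] = level.get(s, 0) + 1
    level = {s: c for s, c in level.items() if c >= min_count}
    counts.update(level)

    for k in range(2, max_len + 1):
        frequent_prev = set(level)
        # join step: (k-1)-itemsets sharing a (k-2)-prefix in sorted order
        prev_sorted = sorted(tuple(sorted(s)) for s in frequent_prev)
        candidates: set[frozenset[str]] = set()
        for i, a in enumerate(prev_sorted):
            for b in prev_sorted[i + 1:]:
                if a[:-1] != b[:-1]:
                    break  # sorted prefixes diverge; later b only diverge more
                cand = frozenset(a) | frozenset(b)
                # prune: every (k-1)-subset must be frequent
                if all(cand - {x} in frequent_prev for x in cand):
                    candidates.add(cand)
        if not candidates:
            break
        level = {}
        for t in transactions:
            if len(t) < k:
                continue
            for cand in candidates:
                if cand <= t:
                    level[cand] = level.get(cand, 0) + 1
        level = {s: c for s, c in level.items() if c >= min_count}
        counts.update(level)
        if not level:
            break
    return counts


def rule_metrics(counts: dict[frozenset[str], int], n: int,
                 antecedent: frozenset[str],
                 consequent: frozenset[str]) -> tuple[float, float, float, int]:
    """Support, confidence, lift and joint frequency for X -> Y.

    ``counts`` must cover X, Y and X ∪ Y (absent keys count as zero joint
    occurrences). Zero antecedent count makes confidence undefined; zero
    consequent count makes lift undefined; both are hard errors.
    """
    antecedent, consequent = frozenset(antecedent), frozenset(consequent)
    if antecedent & consequent:
        raise MiningError("antecedent and consequent must be disjoint")
    if n <= 0:
        raise MiningError("n must be positive")
    cx = counts.get(antecedent, 0)
    cy = counts.get(consequent, 0)
    if cx == 0:
        raise MiningError(f"confidence undefined: antecedent {sorted(antecedent)} never occurs")
    if cy == 0:
        raise MiningError(f"lift undefined: consequent {sorted(consequent)} never occurs")
    cxy = counts.get(antecedent | consequent, 0)
    support = cxy / n
    confidence = cxy / cx
    lift = confidence / (cy / n)
    return support, confidence, lift, cxy


def _rank_key(rule: AssociationRule):
    # support desc, then confidence desc, then lexicographic itemsets
    return (-rule.support, -rule.confidence, rule.antecedent, rule.consequent)


def mine_rules(corpus: Corpus, rule_len: int = 2, min_support: float = 0.0,
               min_confidence: float = 0.0) -> list[AssociationRule]:
    """Mine one rule per frequent pair (``rule_len=2``) or triple (``rule_len=3``).

    Each unordered itemset is reported in a single orientation:

    * pairs: the direction with the higher confidence, i.e. the lower-count
      herb as antecedent (lexicographic antecedent on ties);
    * triples: the 2 -> 1 partition with the highest confidence among the
      three (lexicographically smallest antecedent on ties).

    Rules failing ``min_support`` / ``min_confidence`` are dropped. Ranking
    is stable: support descending, confidence descending, then lexicographic
    itemset order.
    """
    if rule_len not in (2, 3):
        raise MiningError(f"rule_len must be 2 or 3, got {rule_len}")
    if not (0.0 <= min_support <= 1.0 and 0.0 <= min_confidence <= 1.0):
        raise MiningError("thresholds must lie in [0, 1]")

    counts = count_itemsets(corpus, max_len=rule_len)
    n = corpus.n
    rules: list[AssociationRule] = []
    for itemset in counts:
        if len(itemset) != rule_len:
            continue
        best: AssociationRule | None = None
        for consequent_items in combinations(sorted(itemset), 1):
            consequent = frozenset(consequent_items)
            antecedent = itemset - consequent
            s, c, l, f = rule_metrics(counts, n, antecedent, consequent)
            cand = AssociationRule(tuple(sorted(antecedent)), tuple(sorted(consequent)),
                                   s, c, l, f)
            if best is None or cand.confidence > best.confidence or (
                cand.confidence == best.confidence and cand.antecedent < best.antecedent
            ):
                best = cand
        assert best is not None
        if best.support >= min_support and best.confidence >= min_confidence:
            rules.append(best)
    rules.sort(key=_rank_key)
    return rules


def top_rules(rules: list[AssociationRule], k: int) -> list[AssociationRule]:
    """First ``k`` rules of the stable ranking (fewer if fewer exist)."""
    if k < 1:
        raise MiningError("k must be >= 1")
    return list(rules[:k])


def rules_to_frame(rules: list[AssociationRule]) -> pd.DataFrame:
    """Rules as a DataFrame with full-precision metrics."""
    return pd.DataFrame(
        [
            {
                "antecedent": "+".join(r.antecedent),
                "consequent": "+".join(r.consequent),
                "support": r.support,
                "confidence": r.confidence,
                "lift": r.lift,
                "frequency": r.frequency,
            }
            for r in rules
        ],
        columns=["antecedent", "consequent", "support", "confidence", "lift", "frequency"],
    )


def write_rules(rules: list[AssociationRule], path: str | Path, sep: str = "\t") -> None:
    """Write rules as delimited text in deterministic (ranked) order."""
    rules_to_frame(rules).to_csv(path, sep=sep, index=False)
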