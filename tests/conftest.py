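"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths: itemset
counts by scanning every subset against every transaction, and modularity by
a naive double loop over the full formula. They are the ground truth the
optimized implementations are checked against.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from herbnet.corpus import Corpus, Prescription


def make_corpus(transactions, route="internal", annotations=None) -> Corpus:
    """Corpus from an iterable of herb collections."""
    ps = [
        Prescription(f"p{i + 1:03d}", route, frozenset(t))
        for i, t in enumerate(transactions)
    ]
    return Corpus(ps, dict(annotations or {}))


def oracle_itemset_counts(transactions, max_len):
    """Count every itemset of size <= max_len by testing all subsets of all
    transactions — no pruning, no cleverness."""
    universe = sorted(set().union(*map(set, transactions)))
    counts = {}
    for k in range(1, max_len + 1):
        for combo in combinations(universe, k):
            s = frozenset(combo)
            c = sum(1 for t in transactions if s <= set(t))
            if c:
                counts[s] = c
    return counts


def oracle_modularity(graph, assignment, resolution=1.0):
    """Naive O(n^2) evaluation of Q over the dense adjacency matrix."""
    nodes = sorted(graph.nodes, key=str)
    n = len(nodes)
    a = np.zeros((n, n))
    idx = {v: i for i, v in enumerate(nodes)}
    for u, v, w in graph.edges(data="weight", default=1.0):
        if u == v:
            a[idx[u], idx[u]] += 2.0 * w
        else:
            a[idx[u], idx[v]] += w
            a[idx[v], idx[u]] += w
    k = a.sum(axis=1)
    two_m = a.sum()
    q = 0.0
    for i in range(n):
        for j in range(n):
            if assignment[nodes[i]] == assignment[nodes[j]]:
                q += a[i, j] - resolution * k[i] * k[j] / two_m
    return q / two_m


def random_corpus(rng, n_herbs, n_transactions, max_size=8) -> Corpus:
    """Seeded random corpus for oracle-equivalence checks."""
    herbs = [f"h{i:02d}" for i in range(n_herbs)]
    transactions = []
    for _ in range(n_transactions):
        size = int(rng.integers(1, max_size + 1))
        transactions.append(rng.choice(herbs, size=min(size, n_herbs), replace=False))
    return make_corpus(transactions)


@pytest.fixture
def tiny_corpus() -> Corpus:
    """Three transactions {A,B}, {A,B}, {A,C} used by hand-count examples."""
    return make_corpus([{"A", "B"}, {"A", "B"}, {"A", "C"}])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
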