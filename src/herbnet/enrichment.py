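"""Meridian-tropism enrichment of network modules by label permutation.

For each module and each of the 12 meridians, the *preference ratio* is the
fraction of the module's herbs whose meridian set contains that meridian
(each herb counts once, regardless of how often it is prescribed; herbs with
an empty meridian set still count in the denominator). The null distribution
is obtained by shuffling module labels across herbs — module sizes are
preserved, meridian sets ride with their herbs — and recomputing the ratios;
one-sided add-one empirical p-values are taken for excess (high) and deficit
(low), and each tail's 12 meridian tests are Benjamini–Hochberg adjusted
separately within each module.

Because the ratio lives on a lattice of multiples of 1/module_size, the
permutation p-values are discrete and therefore conservative: P(p <= a) equals
the largest attainable level below a, not a itself. Calibration checks must
compare against the attainable level (see :func:`attainable_level`).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import MERIDIANS, HerbAnnotation


class EnrichmentError(ValueError):
    """Raised on inconsistent assignment/annotation inputs."""


def meridian_ratio(assignment: Mapping[str, int],
                   annotations: Mapping[str, HerbAnnotation],
                   module: int, meridian: str) -> float:
    """Fraction of the module's herbs carrying the meridian flag."""
    members = [h for h, m in assignment.items() if m == module]
    if not members:
        raise EnrichmentError(f"module {module!r} is empty")
    missing = [h for h in members if h not in annotations]
    if missing:
        raise EnrichmentError(f"herbs missing from annotations: {sorted(missing)[:5]}")
    return sum(1 for h in members if meridian in annotations[h].meridians) / len(members)


def fdr_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} m * p_(j) / j over the ascending ordering, capped
    at 1. Inputs must lie in (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise EnrichmentError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def _module_layout(assignment: Mapping[str, int],
                   annotations: Mapping[str, HerbAnnotation]):
    """Herb order, boolean flag matrix, module labels and contiguous slices."""
    herbs = sorted(assignment)
    missing = [h for h in herbs if h not in annotations]
    if missing:
        raise EnrichmentError(f"herbs missing from annotations: {sorted(missing)[:5]}")
    flags = np.array(
        [[m in annotations[h].meridians for m in MERIDIANS] for h in herbs], dtype=float
    )
    modules = sorted(set(assignment.values()))
    # order herbs by module so a permutation of row indices + fixed slices
    # is exactly "shuffle module labels across herbs, sizes preserved"
    by_module = sorted(range(len(herbs)), key=lambda i: (assignment[herbs[i]], herbs[i]))
    flags = flags[by_module]
    sizes = [sum(1 for h in herbs if assignment[h] == m) for m in modules]
    bounds = np.cumsum([0, *sizes])
    slices = {m: slice(int(bounds[i]), int(bounds[i + 1])) for i, m in enumerate(modules)}
    return flags, modules, slices


def permuted_ratios(assignment: Mapping[str, int],
                    annotations: Mapping[str, HerbAnnotation],
                    n_perm: int, seed: int) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Observed and label-permutation ratios for every (module, meridian).

    Returns ``(observed, null, modules)`` where ``observed`` has shape
    (n_modules, 12) and ``null`` has shape (n_perm, n_modules, 12).
    """
    if n_perm < 1:
        raise EnrichmentError("n_perm must be >= 1")
    flags, modules, slices = _module_layout(assignment, annotations)
    observed = np.stack([flags[slices[m]].mean(axis=0) for m in modules])
    rng = np.random.default_rng(seed)
    n_herbs = flags.shape[0]
    null = np.empty((n_perm, len(modules), len(MERIDIANS)))
    for b in range(n_perm):
        perm = rng.permutation(n_herbs)
        shuffled = flags[perm]
        for i, m in enumerate(modules):
            null[b, i] = shuffled[slices[m]].mean(axis=0)
    return observed, null, modules


def permutation_test(assignment: Mapping[str, int],
                     annotations: Mapping[str, HerbAnnotation],
                     n_perm: int = 10_000, seed: int = 0,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Module x meridian enrichment table with permutation p- and BH q-values.

    One row per (module, meridian): observed preference ratio, the null mean,
    add-one one-sided p-values ``p_high`` (excess) and ``p_low`` (deficit),
    per-module per-tail BH q-values, and the call ``direction`` in
    {``high``, ``low``, ``none``} at level ``alpha``. Deterministic given
    ``seed``.
    """
    observed, null, modules = permuted_ratios(assignment, annotations, n_perm, seed)
    p_high = (1 + (null >= observed[None]).sum(axis=0)) / (1 + n_perm)
    p_low = (1 + (null <= observed[None]).sum(axis=0)) / (1 + n_perm)
    null_mean = null.mean(axis=0)

    rows = []
    for i, m in enumerate(modules):
        q_high = fdr_adjust(p_high[i])
        q_low = fdr_adjust(p_low[i])
        for j, meridian in enumerate(MERIDIANS):
            if q_high[j] < alpha:
                direction = "high"
            elif q_low[j] < alpha:
                direction = "low"
            else:
                direction = "none"
            rows.append(
                {
                    "module": m,
                    "meridian": meridian,
                    "observed_ratio": observed[i, j],
                    "null_mean": null_mean[i, j],
                    "p_high": p_high[i, j],
                    "p_low": p_low[i, j],
                    "q_high": q_high[j],
                    "q_low": q_low[j],
                    "direction": direction,
                    "n_perm": n_perm,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)


def attainable_level(null: np.ndarray, alpha: float) -> float:
    """Exact expected rejection rate of the add-one test at nominal ``alpha``.

    Each permuted draw is scored as a pseudo-observation against the whole
    null sample (itself included, which reproduces the add-one counting), and
    the fraction with p <= alpha is returned — the level the discrete test
    actually attains, always <= alpha. ``null`` is a 1-D sample for one
    (module, meridian) cell or any stack thereof along leading axes.
    """
    null = np.asarray(null, dtype=float)
    flat = null.reshape(-1, null.shape[-1]) if null.ndim > 1 else null[None]
    n_perm = flat.shape[-1]
    rates = []
    for row in flat:
        order = np.sort(row)
        # count of draws >= v via searchsorted on the sorted sample
        ge = n_perm - np.searchsorted(order, row, side="left")
        p = ge / (1 + n_perm)  # = (1 + #{others >= v}) / (1 + n_perm) incl. self
        rates.append(np.mean(p <= alpha))
    return float(np.mean(rates))
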