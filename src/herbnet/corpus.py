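"""Domain model for herb–prescription corpora.

A *corpus* is a set of prescriptions (transactions), each holding a set of
herbs (items), together with per-herb annotations: the herb's Latin name,
its traditional pharmacological category (an integer code 1–20) and its
meridian tropism — the subset of the 12 organ meridians the herb is held
to act on.

Prescriptions carry a route of administration (``internal`` / ``external``);
mining is normally restricted to one route because the mechanism of action
differs between decoctions taken internally and topical applications.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical two-letter codes of the 12 organ meridians: Liver, Heart,
#: Pericardium, Spleen, Lung, Kidney, Gall bladder, Small intestine,
#: Triple energizer, Stomach, Large intestine, Bladder.
MERIDIANS: tuple[str, ...] = (
    "LR", "HT", "PC", "SP", "LU", "KI", "GB", "SI", "TE", "ST", "LI", "BL",
)

ROUTES: tuple[str, str] = ("internal", "external")

_TRUE_FLAGS = {"y", "1", "true", "yes"}
_FALSE_FLAGS = {"", "n", "0", "false", "no", "nan"}


class CorpusError(ValueError):
    """Raised for malformed transaction or annotation inputs."""


class InfeasibleCountSpec(ValueError):
    """Raised when a :class:`CountSpec` cannot be realized by any corpus."""


@dataclass(frozen=True)
class HerbAnnotation:
    """Annotation record for one herb.

    Parameters
    ----------
    herb_id
        Opaque identifier; unique within an annotation table.
    latin_name
        Botanical (Latin) name, informational only.
    meridians
        Subset of the 12 canonical meridian codes.
    category
        Traditional pharmacological category, integer in 1–20
        (e.g. 17 = tonifying and replenishing medicinal).
    """

    herb_id: str
    latin_name: str = ""
    meridians: frozenset[str] = frozenset()
    category: int = 1

    def __post_init__(self) -> None:
        bad = set(self.meridians) - set(MERIDIANS)
        if bad:
            raise CorpusError(f"unknown meridian code(s) {sorted(bad)} for herb {self.herb_id!r}")
        if not 1 <= int(self.category) <= 20:
            raise CorpusError(f"category {self.category} for herb {self.herb_id!r} outside 1-20")
        object.__setattr__(self, "meridians", frozenset(self.meridians))


@dataclass(frozen=True)
class Prescription:
    """One prescription: an identifier, a route, and a *set* of herbs.

    Herb sets have set semantics — within-prescription repetition of a herb
    carries no weight (dose is never modelled), so duplicates collapse.
    """

    prescription_id: str
    route: str
    herbs: frozenset[str]

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise CorpusError(
                f"unknown route {self.route!r} for prescription {self.prescription_id!r}"
            )
        if not self.herbs:
            raise CorpusError(f"prescription {self.prescription_id!r} has no herbs")
        object.__setattr__(self, "herbs", frozenset(self.herbs))


@dataclass
class Corpus:
    """A transaction corpus plus herb annotations.

    Attributes
    ----------
    prescriptions
        The transactions, in a stable order.
    annotations
        Mapping herb_id -> :class:`HerbAnnotation`; may be empty and may
        annotate herbs that never occur.
    """

    prescriptions: list[Prescription]
    annotations: dict[str, HerbAnnotation] = field(default_factory=dict)

    @property
    def n(self) -> int:
        """Number of transactions N."""
        return len(self.prescriptions)

    @property
    def herbs(self) -> frozenset[str]:
        """Herb universe H: every herb occurring in a prescription or annotated."""
        out: set[str] = set(self.annotations)
        for p in self.prescriptions:
            out |= p.herbs
        return frozenset(out)

    def transactions(self) -> list[frozenset[str]]:
        """Herb sets only, in corpus order."""
        return [p.herbs for p in self.prescriptions]


def read_transactions(path: str | Path, sep: str | None = None) -> Corpus:
    """Read a delimited transaction table into a :class:`Corpus`.

    The file must have a header with columns ``prescription_id``, ``herb_id``
    and ``route`` and one row per prescription–herb occurrence. The delimiter
    is auto-detected unless ``sep`` is given. Duplicate (prescription, herb)
    rows collapse with a logged warning; a prescription spanning two route
    values is a hard error, as is an unknown route token.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, engine="python", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise CorpusError(f"empty transaction file: {path}") from None
    required = {"prescription_id", "herb_id", "route"}
    missing = required - set(df.columns)
    if missing:
        raise CorpusError(f"transaction file {path} missing column(s) {sorted(missing)}")
    if df.empty:
        raise CorpusError(f"empty transaction file: {path}")

    herbs_of: dict[str, set[str]] = {}
    route_of: dict[str, str] = {}
    order: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        pid, hid, route = str(row.prescription_id), str(row.herb_id), str(row.route)
        if route not in ROUTES:
            raise CorpusError(f"unknown route {route!r} in row {i + 2} of {path}")
        if pid in route_of:
            if route_of[pid] != route:
                raise CorpusError(
                    f"prescription {pid!r} carries two route values "
                    f"({route_of[pid]!r} and {route!r}) in {path}"
                )
        else:
            route_of[pid] = route
            herbs_of[pid] = set()
            order.append(pid)
        if hid in herbs_of[pid]:
            logger.warning("duplicate herb %r in prescription %r collapsed", hid, pid)
        herbs_of[pid].add(hid)

    prescriptions = [
        Prescription(pid, route_of[pid], frozenset(herbs_of[pid])) for pid in sorted(order)
    ]
    return Corpus(prescriptions)


def write_transactions(corpus: Corpus, path: str | Path, sep: str = "\t") -> None:
    """Write the transaction table (one row per prescription–herb pair)."""
    rows = [
        {"prescription_id": p.prescription_id, "herb_id": h, "route": p.route}
        for p in corpus.prescriptions
        for h in sorted(p.herbs)
    ]
    pd.DataFrame(rows, columns=["prescription_id", "herb_id", "route"]).to_csv(
        path, sep=sep, index=False
    )


def read_annotations(path: str | Path, sep: str | None = None) -> dict[str, HerbAnnotation]:
    """Read a herb annotation table.

    Expected columns: ``herb_id``, ``latin_name``, ``category`` and one flag
    column per meridian code (``LR`` … ``BL``). Flag values ``Y``/``1``/``true``
    (case-insensitive) mark presence; empty, ``N``, ``0`` or ``false`` mark
    absence. An empty meridian set is legitimate (some herbs carry no recorded
    tropism). Extra columns that are not meridian codes are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, engine="python", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise CorpusError(f"empty annotation file: {path}") from None
    base = {"herb_id", "latin_name", "category"}
    missing = base - set(df.columns)
    if missing:
        raise CorpusError(f"annotation file {path} missing column(s) {sorted(missing)}")
    extra = set(df.columns) - base - set(MERIDIANS)
    if extra:
        raise CorpusError(f"unknown meridian column(s) {sorted(extra)} in {path}")

    out: dict[str, HerbAnnotation] = {}
    for i, row in df.iterrows():
        hid = str(row["herb_id"])
        if hid in out:
            raise CorpusError(f"duplicate herb_id {hid!r} in {path}")
        try:
            category = int(str(row["category"]))
        except ValueError:
            raise CorpusError(f"non-numeric category {row['category']!r} for herb {hid!r}") from None
        flags = set()
        for m in MERIDIANS:
            if m not in df.columns:
                continue
            val = str(row[m]).strip().lower()
            if val in _TRUE_FLAGS:
                flags.add(m)
            elif val not in _FALSE_FLAGS:
                raise CorpusError(f"unrecognized flag {row[m]!r} in column {m} for herb {hid!r}")
        out[hid] = HerbAnnotation(hid, str(row["latin_name"]), frozenset(flags), category)
    return out


def write_annotations(annotations: Mapping[str, HerbAnnotation], path: str | Path,
                      sep: str = "\t") -> None:
    """Write an annotation table in the format :func:`read_annotations` expects."""
    rows = []
    for hid in sorted(annotations):
        a = annotations[hid]
        row = {"herb_id": a.herb_id, "latin_name": a.latin_name, "category": a.category}
        for m in MERIDIANS:
            row[m] = "Y" if m in a.meridians else ""
        rows.append(row)
    cols = ["herb_id", "latin_name", "category", *MERIDIANS]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)


def filter_by_route(corpus: Corpus, route: str) -> Corpus:
    """Return the sub-corpus of prescriptions with the given route.

    Annotations are carried over unchanged; per-prescription herb sets are
    preserved exactly.
    """
    if route not in ROUTES:
        raise CorpusError(f"unknown route {route!r}")
    kept = [p for p in corpus.prescriptions if p.route == route]
    return Corpus(kept, dict(corpus.annotations))


# ---------------------------------------------------------------------------
# Fixture corpora realizing exact occurrence counts
# ---------------------------------------------------------------------------

@dataclass
class CountSpec:
    """Exact marginal and joint occurrence counts a fixture corpus must realize.

    ``joints`` maps herb sets of size 2 or 3 to required co-occurrence counts.
    Used to rebuild corpora with the statistics of published frequency tables
    so the mining stage can be exercised against printed values.
    """

    n: int
    marginals: dict[str, int] = field(default_factory=dict)
    joints: dict[frozenset[str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.joints = {frozenset(k): v for k, v in self.joints.items()}
        if self.n < 0 or any(v < 0 for v in self.marginals.values()) or any(
            v < 0 for v in self.joints.values()
        ):
            raise InfeasibleCountSpec("negative counts are not allowed")
        for herb, cnt in self.marginals.items():
            if cnt > self.n:
                raise InfeasibleCountSpec(f"marginal of {herb!r} ({cnt}) exceeds N={self.n}")
        for items, cnt in self.joints.items():
            if len(items) not in (2, 3):
                raise InfeasibleCountSpec(f"joint itemset {sorted(items)} must have size 2 or 3")
            for herb in items:
                if herb in self.marginals and cnt > self.marginals[herb]:
                    raise InfeasibleCountSpec(
                        f"joint count {cnt} for {sorted(items)} exceeds marginal of {herb!r}"
                    )


def build_fixture_corpus(spec: CountSpec, filler_policy: str = "dummy_herb",
                         route: str = "internal") -> Corpus:
    """Deterministically construct a corpus realizing a :class:`CountSpec`.

    Realization is block-wise: one block of transactions per specified triple
    (the full triple itemset), then per specified pair a block topping its
    count up past what the triples already supplied, then per-herb singleton
    blocks topping up marginals, then padding to exactly ``n`` transactions.
    Padding follows ``filler_policy``: ``"dummy_herb"`` (default) gives every
    pad transaction a fresh dummy herb; ``"empty_pad"`` uses one shared
    placebo herb. Either way pad transactions stay non-empty and never touch
    a specified count.

    Raises :class:`InfeasibleCountSpec` when residual counts go negative or
    the blocks exceed ``n``. Joint structure beyond "pairs nested in a single
    triple" (e.g. two triples sharing a pair) is not realizable block-wise
    and is reported as infeasible.
    """
    if filler_policy not in ("dummy_herb", "empty_pad"):
        raise ValueError(f"unknown filler_policy {filler_policy!r}")

    blocks: list[frozenset[str]] = []

    triples = sorted((k for k in spec.joints if len(k) == 3), key=lambda s: tuple(sorted(s)))
    pairs = sorted((k for k in spec.joints if len(k) == 2), key=lambda s: tuple(sorted(s)))

    for t in triples:
        blocks.extend([t] * spec.joints[t])

    def _cover(itemset: frozenset[str]) -> int:
        return sum(1 for b in blocks if itemset <= b)

    for p in pairs:
        residual = spec.joints[p] - _cover(p)
        if residual < 0:
            raise InfeasibleCountSpec(
                f"pair {sorted(p)} requires {spec.joints[p]} co-occurrences but triple "
                f"blocks already supply {_cover(p)}"
            )
        blocks.extend([p] * residual)

    # unspecified pairs must not be accidentally over-counted by overlapping
    # triples; with disjoint blocks per itemset they only co-occur inside a
    # containing specified itemset, which is the intended semantics.
    for herb in sorted(spec.marginals):
        residual = spec.marginals[herb] - sum(1 for b in blocks if herb in b)
        if residual < 0:
            raise InfeasibleCountSpec(
                f"marginal of {herb!r} ({spec.marginals[herb]}) is below the count "
                f"implied by joint blocks"
            )
        blocks.extend([frozenset({herb})] * residual)

    if len(blocks) > spec.n:
        raise InfeasibleCountSpec(
            f"spec requires {len(blocks)} transactions but N={spec.n}"
        )

    width = max(4, len(str(spec.n)))
    prescriptions = [
        Prescription(f"p{i + 1:0{width}d}", route, b) for i, b in enumerate(blocks)
    ]
    n_pad = spec.n - len(blocks)
    for j in range(n_pad):
        if filler_policy == "dummy_herb":
            herbset = frozenset({f"__filler_{j + 1:0{width}d}"})
        else:
            herbset = frozenset({"__placebo"})
        prescriptions.append(
            Prescription(f"p{len(blocks) + j + 1:0{width}d}", route, herbset)
        )
    return Corpus(prescriptions)


def count_occurrences(corpus: Corpus, itemset: Iterable[str]) -> int:
    """Brute-force count of transactions containing every herb in ``itemset``."""
    items = frozenset(itemset)
    return sum(1 for t in corpus.transactions() if items <= t)
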