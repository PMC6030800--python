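# Methods

## Data model

A corpus is a list of prescriptions, each a *set* of herb identifiers with
a route of administration (internal/external), plus per-herb annotations:
Latin name, a pharmacological category code (1–20, the traditional
classification from exterior-releasing through external-application
medicinals), and the herb's meridian tropism — a subset of the 12 organ
meridians (Liver LR, Heart HT, Pericardium PC, Spleen SP, Lung LU, Kidney
KI, Gall bladder GB, Small intestine SI, Triple energizer TE, Stomach ST,
Large intestine LI, Bladder BL). Within-prescription repetition and dose
carry no information in any stage, so herb sets collapse duplicates at read
time (with a logged warning). Herb identifiers are opaque: botanical-name
normalization is a curation task upstream of this package. A herb used both
internally and externally is one herb; the route belongs to the
prescription. Analyses are run on one route at a time (internal by
default), because the mechanism of action differs by route.

## Association rules

Itemset counting is level-wise apriori with candidate pruning by
anti-monotonicity, exact for all itemsets up to size 3 occurring at least
once. Rule metrics are the standard support / confidence / lift. Two
reporting conventions are fixed here because published tables are otherwise
ambiguous:

- **Orientation.** Each unordered pair is reported once, in the direction
  with the higher confidence — equivalently with the lower-count herb as
  antecedent (lexicographic tie-break). Triples are reported as the 2 → 1
  partition with the highest confidence among the three. This makes the
  reported confidence a deterministic function of the counts.
- **Thresholds.** Defaults are min_support = 0 and min_confidence = 0 with
  ranking by support (then confidence, then lexicographic itemset order);
  both thresholds are configurable. Degenerate thresholds plus ranking
  reproduce "top-k" tables without guessing an unstated cutoff.

Metrics are kept at full precision internally and rounded to 3 decimals
only in rendered tables.

## Fixture corpora from count specifications

Published frequency tables fix N, per-herb marginals and pair/triple joint
counts — enough to determine every rule metric — even when the underlying
transactions are not available. `build_fixture_corpus` realizes a count
specification block-wise: all transactions for each specified triple, then
per specified pair the residual above what triples already supplied, then
singleton top-ups to the marginals, then padding to N (fresh dummy
singleton herbs by default, or one shared placebo herb). Construction is
deterministic, and every build is verifiable by brute-force recounting.
Specifications whose joints overlap beyond "pairs nested in one triple"
(e.g. two triples sharing a pair) are not block-realizable and raise an
infeasibility error; real corpora satisfy such constraint sets through
higher-order overlaps that a fixture does not need to model, since each
published row is checked against its own fixture.

## Co-occurrence network and Louvain

Edges link herbs sharing at least one prescription, weighted by the number
of shared prescriptions; herbs never co-prescribed with another herb are
isolated and excluded from modularity analysis. Modularity is the standard
weighted form with a resolution parameter γ scaling the null term (default
1.0). The Louvain optimizer is implemented in-package so the gain
arithmetic is directly testable against a naive evaluation of the
modularity formula and against exhaustive partition search on small graphs;
networkx is used only as the graph container and GraphML/GEXF exporter.
Determinism: the node sweep order is shuffled by a named seed each pass,
and equal-gain ties go to the smaller community id. Module labels are
canonicalized to 1..k by descending size (ties: smallest member id), so
labels are comparable across runs. The recorded Q is recomputed from the
final assignment with the same modularity routine, never taken from the
optimizer's internal bookkeeping.

## Meridian enrichment

The preference ratio of (module, meridian) is the fraction of the module's
herbs whose meridian set contains the meridian — each herb counts once,
regardless of prescription frequency, and herbs with empty meridian sets
stay in the denominator. (A prescription-frequency-weighted variant is a
plausible alternative; the herb-presence definition is the default because
the ratio describes the module's composition, not its usage volume.) The
null shuffles module labels across herbs — sizes preserved, meridian sets
riding with their herbs — n_perm times (default 10,000). Both one-sided
add-one p-values are reported: p_high = (1 + #{r* ≥ r_obs})/(1 + n_perm)
and symmetrically p_low, so the floor is 1/(n_perm + 1) and p_high + p_low
≥ 1 + 1/(n_perm + 1) (both tails count the observed tie). Within each
module, the 12 meridians are BH-adjusted per tail; a cell is called high
(or low) when the corresponding q < α (default 0.05).

**Discreteness and calibration.** The ratio lives on the lattice of
multiples of 1/module_size, so the permutation p-value is discrete and the
test conservative: P(p ≤ α) equals the largest *attainable* level below α,
not α itself — for modules of a few dozen herbs the attained level at
nominal 0.05 is typically 0.03–0.04. Calibration is therefore checked two
ways: the empirical rejection rate under null annotations must match the
attainable level (computed from the same permutation null by scoring each
permuted draw as a pseudo-observation) within Monte-Carlo error, and must
not exceed the nominal α bound. Comparing the raw rate to α directly would
conflate conservativeness with miscalibration.

## Synthetic corpora

The generator is the simplest process producing block-structured
co-occurrence, which is all the downstream stages assume. Herbs are
partitioned into planted modules; each prescription picks a home module
with probability proportional to module size, draws its size uniformly from
a range, and draws each herb from the home module with probability
p_within, else uniformly from all herbs. Meridian flags are independent
Bernoulli per (herb, meridian) with elevated probabilities in enriched
(module, meridian) cells and a common baseline elsewhere; a null-annotation
generator draws flags with no module structure at all, for type-I
calibration.

Defaults describe a surveyed internal-route alopecia corpus: 312
prescriptions, 255 connected herbs in modules of 58/86/111, prescription
sizes 4–12 (a typical span for multi-herb decoction formulas; no published
value exists), p_within = 0.9, baseline flag probability 0.25, and planted
enrichment LR/KI in module 1 and ST in module 3 at probability 0.8 —
qualitative patterns reported for that corpus, with magnitudes chosen to
be realistic rather than read from a table. Everything is configurable; the
seed fully determines the output.

What the generator does **not** emulate: herb-frequency skew within a
module (all module members are exchangeable), formula-level conventions
such as herb-pair incompatibilities, corpus-level duplication of classic
formulas across publications, and any dependence between prescription size
and module. Tests passing on synthetic corpora therefore validate the
machinery — counting, optimization, calibration — not the sociology of real
prescription data.

## Problem sizes and numerical choices

Oracle-equivalence tests run 30 seeded corpora of ≤ 25 herbs and ≤ 60
transactions against exhaustive enumeration; Louvain is checked against
full partition search on 10-node graphs and against the planted truth (ARI
≥ 0.9 over 5 seeds) on 150-herb, 500-prescription corpora. Calibration uses
200 replicates of a 120-herb, 3-module null corpus at n_perm = 1,000; power
uses 20 replicates with planted LR enrichment (0.9 vs 0.2 baseline, 50-herb
modules) at n_perm = 1,000. The acceptance script uses 100 calibration
replicates and the same fixture, recovery and power settings. Floating-point
ties in Louvain gains are resolved with an absolute 1e-12 tolerance before
the community-id tie-break; BH and modularity are exact arithmetic on
floats with no tolerance knobs.

## Known limitations

- The fixture builder intentionally rejects joint-count systems requiring
  higher-order overlaps; it realizes one published table row at a time.
- Louvain is a greedy heuristic: optimality is guaranteed only where the
  tests enumerate all partitions; on larger graphs the checks are
  lower-bound (never worse than trivial partitions) and recovery-based.
- One published pair row and one published triple row report confidence in
  a non-maximal orientation; under this package's deterministic orientation
  convention those two confidences are reproduced only up to orientation
  (all orientation-symmetric quantities match).
- Enrichment over the 20 pharmacological categories would be a mechanical
  reuse of the same permutation machinery with a different label set, and
  is not wired in.
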