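# herbnet

Mining herb combination patterns in traditional East Asian medicine
prescription corpora: association rules, co-prescription network modules,
and meridian-tropism enrichment.

Multi-herb formulas are the unit of treatment in traditional Chinese and
Korean medicine, and surveys of the clinical literature yield corpora of
prescriptions — each a set of herbs, given by an internal or external route.
`herbnet` answers three questions about such a corpus:

1. **Which herbs are combined?** Each prescription is a transaction over the
   herb universe, and level-wise apriori counting scores every two- and
   three-herb rule X → Y by

   - support = count(X ∪ Y) / N,
   - confidence = count(X ∪ Y) / count(X),
   - lift = confidence / (count(Y) / N),

   with each unordered itemset reported in its maximum-confidence
   orientation and ranked by support.

2. **How do combinations organize globally?** Herbs co-occurring in at least
   one prescription are linked, weighted by the number of shared
   prescriptions, and the weighted modularity
   Q = (1/2m) Σ_ij [A_ij − γ k_i k_j / 2m] δ(c_i, c_j)
   is maximized by a seeded, deterministic Louvain optimizer (resolution γ,
   default 1.0). Herbs never co-prescribed with another herb are excluded.

3. **Do modules have a therapeutic orientation?** For each module and each
   of the 12 organ meridians (LR, HT, PC, SP, LU, KI, GB, SI, TE, ST, LI,
   BL), the preference ratio is the fraction of the module's herbs whose
   recorded meridian tropism includes that meridian. Module labels are
   permuted across herbs (10,000 times by default) to get a null; one-sided
   add-one p-values for excess and deficit are Benjamini–Hochberg adjusted
   per module and per tail.

A synthetic-corpus generator with planted modules and planted meridian
enrichment provides ground truth for validating recovery and calibrating
the permutation test, and a fixture builder constructs corpora that realize
exact published marginal/joint occurrence counts so the mining stage can be
checked against printed tables.

## Worked example

`examples/mine_association_rules.py` rebuilds a 312-prescription fixture in
which *Polygonum multiflorum* occurs 175 times, *Angelica sinensis* 171
times, and the two co-occur 120 times, then runs the full mining stage:

```
corpus: 312 prescriptions
Angelica -> Polygonum: support=0.385 confidence=0.702 lift=1.251 frequency=120
Ligusticum+Polygonum -> Angelica: support=0.234 confidence=0.890 lift=1.624 frequency=73
```

38.5% of prescriptions contain both herbs; 70.2% of the prescriptions with
*Angelica* also contain *Polygonum*; lift 1.251 > 1 means the pair
co-occurs 25% more often than independence predicts. The second line is the
strongest three-herb rule: when *Ligusticum* and *Polygonum* appear
together, *Angelica* joins them 89% of the time.

`examples/detect_modules.py` generates a synthetic corpus (255 herbs in
planted modules of 58/86/111, 312 prescriptions) and recovers the structure:

```
network: 255 connected herbs, 7055 edges, 0 isolated
modules: 3 with sizes [110, 86, 59] (planted: 58, 86, 111)
modularity Q = 0.504 at resolution 1.0
```

`examples/meridian_enrichment.py` then detects the planted Liver/Kidney
enrichment (module 3 after canonical size-ordered relabeling) and Stomach
enrichment:

```
module meridian direction ratio null_mean q
     1       ST      high  0.83      0.53 0.0012
     3       LR      high  0.83      0.41 0.0005999
     3       KI      high  0.73      0.34 0.0005999
...
```

`examples/full_pipeline.py` runs everything end to end and prints the run
report. The same pipeline is available from the shell:

```sh
herbnet simulate --seed 7
herbnet run --transactions synthetic_transactions.tsv \
            --annotations synthetic_annotations.tsv --outdir run/
herbnet mine run/../synthetic_transactions.tsv --rule-len 2 --top-k 10
```

## Layout

- `src/herbnet/corpus.py` — domain types, transaction/annotation I/O, route
  filtering, fixture-corpus construction from count specifications
- `src/herbnet/datasets.py` — published occurrence counts and fixture helpers
- `src/herbnet/mining.py` — apriori counting and rule scoring
- `src/herbnet/network.py` — co-occurrence network, modularity, Louvain,
  GraphML/GEXF export
- `src/herbnet/enrichment.py` — preference ratios, permutation test, BH FDR
- `src/herbnet/synthetic.py` — planted-structure corpus generator
- `src/herbnet/pipeline.py`, `src/herbnet/cli.py` — orchestration and the
  `herbnet` command
- `docs/methods.md` — models, conventions and numerical choices
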