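"""End-to-end orchestration: read -> filter -> mine -> network -> modules -> enrichment.

Every stage writes its output eagerly, so a late failure (e.g. a missing
annotation file at the enrichment stage) leaves earlier artifacts on disk.
All randomness flows through two named seeds (``louvain_seed``,
``perm_seed``); the manifest echoes the full configuration so any run can be
reproduced bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import corpus as corpus_mod
from .corpus import Corpus, filter_by_route, read_annotations, read_transactions
from .enrichment import permutation_test
from .mining import mine_rules, top_rules, write_rules
from .network import (
    build_cooccurrence_network,
    export_network,
    louvain_partition,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage-named pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    transactions: str
    annotations: str | None = None
    outdir: str = "herbnet_run"
    route: str = "internal"
    rule_lens: tuple[int, ...] = (2, 3)
    min_support: float = 0.0
    min_confidence: float = 0.0
    top_k: int = 10
    resolution: float = 1.0
    louvain_seed: int = 0
    n_perm: int = 10_000
    perm_seed: int = 0
    alpha: float = 0.05
    sep: str | None = None
    weighted_ratio: bool = False  # reserved: prescription-frequency weighting

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "rule_lens" in raw:
            raw["rule_lens"] = tuple(raw["rule_lens"])
        return cls(**raw)


def run_pipeline(config: RunConfig, corpus: Corpus | None = None) -> dict:
    """Execute all stages; returns the manifest dict.

    ``corpus`` may be passed directly (e.g. a synthetic corpus) instead of
    reading ``config.transactions``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("herbnet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest: dict = {"config": asdict(config), "stages": {}}
    try:
        # --- read & filter -------------------------------------------------
        try:
            if corpus is None:
                corpus = read_transactions(config.transactions, sep=config.sep)
            corpus = filter_by_route(corpus, config.route)
            if corpus.n == 0:
                raise corpus_mod.CorpusError(
                    f"no prescriptions with route {config.route!r}"
                )
        except (OSError, ValueError) as e:
            raise PipelineError("read", str(e)) from e
        herb_count = len({h for p in corpus.prescriptions for h in p.herbs})
        manifest["stages"]["read"] = {"n_prescriptions": corpus.n, "n_herbs": herb_count}
        logger.info("read: N=%d prescriptions, %d herbs (route=%s)",
                    corpus.n, herb_count, config.route)
        _write_manifest(manifest, outdir)

        # --- rule mining ---------------------------------------------------
        try:
            for rule_len in config.rule_lens:
                rules = mine_rules(corpus, rule_len, config.min_support,
                                   config.min_confidence)
                write_rules(rules, outdir / f"rules_len{rule_len}.tsv")
                manifest["stages"][f"rules_len{rule_len}"] = {"n_rules": len(rules)}
                logger.info("mining: %d rules of length %d", len(rules), rule_len)
        except ValueError as e:
            raise PipelineError("mine", str(e)) from e
        _write_manifest(manifest, outdir)

        # --- network & modules --------------------------------------------
        try:
            network = build_cooccurrence_network(corpus)
            partition = louvain_partition(network, config.resolution,
                                          config.louvain_seed)
            export_network(network, corpus, partition, outdir / "network")
            with open(outdir / "partition.tsv", "w") as fh:
                fh.write("herb_id\tmodule\n")
                for herb in sorted(partition.assignment):
                    fh.write(f"{herb}\t{partition.assignment[herb]}\n")
        except ValueError as e:
            raise PipelineError("network", str(e)) from e
        sizes = partition.sizes()
        manifest["stages"]["network"] = {
            "n_nodes": network.graph.number_of_nodes(),
            "n_edges": network.graph.number_of_edges(),
            "n_isolated": len(network.isolated),
            "module_sizes": {str(k): v for k, v in sorted(sizes.items())},
            "modularity": partition.q,
        }
        logger.info("network: %d nodes, %d edges, %d isolated; %d modules, Q=%.4f",
                    network.graph.number_of_nodes(), network.graph.number_of_edges(),
                    len(network.isolated), len(sizes), partition.q)
        _write_manifest(manifest, outdir)

        # --- enrichment ----------------------------------------------------
        try:
            annotations = dict(corpus.annotations)
            if config.annotations is not None:
                annotations.update(read_annotations(config.annotations, sep=config.sep))
            if not annotations:
                raise corpus_mod.CorpusError("no herb annotations available")
            table = permutation_test(partition.assignment, annotations,
                                     n_perm=config.n_perm, seed=config.perm_seed,
                                     alpha=config.alpha)
            table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        except (OSError, ValueError) as e:
            raise PipelineError("enrich", str(e)) from e
        n_calls = int((table["direction"] != "none").sum())
        manifest["stages"]["enrichment"] = {"n_significant": n_calls}
        logger.info("enrichment: %d significant (module, meridian) calls", n_calls)
        manifest["complete"] = True
        _write_manifest(manifest, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def summarize_run(outdir: str | Path) -> str:
    """Human-readable report of a completed run directory."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise PipelineError("summarize", f"no manifest in {outdir}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    stages = manifest.get("stages", {})
    if "network" not in stages or "read" not in stages:
        raise PipelineError("summarize", f"incomplete run directory {outdir}")

    lines = []
    read = stages["read"]
    lines.append(f"Corpus: {read['n_prescriptions']} prescriptions, "
                 f"{read['n_herbs']} herbs (route={manifest['config']['route']})")

    import pandas as pd  # local import keeps module import light

    for rule_len in manifest["config"]["rule_lens"]:
        path = outdir / f"rules_len{rule_len}.tsv"
        if not path.exists():
            raise PipelineError("summarize", f"missing {path.name}")
        df = pd.read_csv(path, sep="\t")
        k = manifest["config"]["top_k"]
        lines.append(f"\nTop {min(k, len(df))} rules (itemset length {rule_len}):")
        lines.append(f"{'antecedent':<34}{'consequent':<22}"
                     f"{'support':>8}{'confidence':>11}{'lift':>7}{'freq':>6}")
        for _, r in df.head(k).iterrows():
            lines.append(
                f"{r['antecedent']:<34}{r['consequent']:<22}"
                f"{r['support']:>8.3f}{r['confidence']:>11.3f}{r['lift']:>7.3f}"
                f"{int(r['frequency']):>6d}"
            )

    net = stages["network"]
    sizes = ", ".join(f"module {k}: {v}" for k, v in net["module_sizes"].items())
    lines.append(f"\nNetwork: {net['n_nodes']} connected herbs, {net['n_edges']} edges, "
                 f"{net['n_isolated']} isolated (excluded)")
    lines.append(f"Modules ({len(net['module_sizes'])}): {sizes}")
    lines.append(f"Modularity Q = {net['modularity']:.3f} "
                 f"(resolution {manifest['config']['resolution']})")

    enr_path = outdir / "enrichment.tsv"
    if enr_path.exists():
        df = pd.read_csv(enr_path, sep="\t")
        sig = df[df["direction"] != "none"]
        lines.append("\nSignificant meridian preferences (BH per module, per tail):")
        if sig.empty:
            lines.append("  none")
        else:
            for _, r in sig.iterrows():
                lines.append(
                    f"  module {r['module']}: {r['meridian']} {r['direction']} "
                    f"(ratio {r['observed_ratio']:.2f} vs null {r['null_mean']:.2f}, "
                    f"q={min(r['q_high'], r['q_low']):.4g})"
                )
    return "\n".join(lines)
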