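"""End-to-end orchestration: config in, deterministic artifact tree out.

Stages: load -> (optional) quantile normalization -> paired DE -> per-
condition correlation networks -> edge partition -> alias resolution and
clock-target annotation -> per-condition topology -> candidate ranking.
Every stage is a pure function of its inputs and the config; the only
stochastic element in the project is the synthetic-cohort generator, driven
by the single seed in the config.  Re-running with the same config and seed
reproduces every artifact byte-identically (no timestamps are written).

One structured log line per stage records input/output dimensions so that
filtering attrition is auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import algebra, corrnet, diffexpr, expression, topology, validation

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Abort marker carrying the failing stage name and a machine code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    expression: str = ""
    samplesheet: str = ""
    target_map: str = "validated"  # path to a mirna<TAB>gene TSV, or the builtin map
    aliases: str = ""              # optional miRBase-style alias file
    second_expression: str = ""    # optional cross-check dataset
    second_samplesheet: str = ""
    r_cut: float = corrnet.R_CUT_MAIN
    alpha: float = 0.05
    fc_cut: float = 1.5
    fdr_cut: float = 0.05
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    quantile_normalize: bool = False
    seed: int = 0
    out_dir: str = "clocknet_run"

    def __post_init__(self):
        if not 0.0 < self.r_cut < 1.0:
            raise ValueError(f"r_cut must lie in (0, 1), got {self.r_cut}")
        for name in ("alpha", "fc_cut", "fdr_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.weights = tuple(float(w) for w in self.weights)
        if len(self.weights) != 3 or any(w < 0 for w in self.weights):
            raise ValueError("weights must be 3 nonnegative numbers")

    def to_yaml(self, path) -> None:
        obj = dataclasses.asdict(self)
        obj["weights"] = list(self.weights)
        Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        obj = yaml.safe_load(Path(path).read_text())
        if "weights" in obj:
            obj["weights"] = tuple(obj["weights"])
        return cls(**obj)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the artifact manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, object] = {}
    artifacts: list[Path] = []

    def fail(stage, code, message):
        raise StageError(stage, code, message)

    # --- load -------------------------------------------------------------
    try:
        pset = expression.load_paired_set(config.expression, config.samplesheet)
    except (OSError, ValueError) as err:
        fail("load", "bad_input", str(err))
    logger.info("stage=load features=%d patients=%d", len(pset.symbols), pset.n_patients)
    counts["features"] = len(pset.symbols)
    counts["patients"] = pset.n_patients

    # --- annotation inputs (fail early: a missing map aborts the run) -----
    try:
        if config.target_map == "validated":
            targets = algebra.TargetMap.validated()
        else:
            targets = algebra.TargetMap.from_tsv(config.target_map)
    except (OSError, ValueError) as err:
        fail("annotation", "target_map", str(err))
    aliases = None
    if config.aliases:
        try:
            aliases = algebra.AliasTable.from_file(config.aliases)
        except OSError as err:
            fail("annotation", "aliases", str(err))

    # --- normalization ----------------------------------------------------
    if config.quantile_normalize:
        try:
            pset = expression.quantile_normalize(pset)
        except ValueError as err:
            fail("normalize", "invalid", str(err))
        logger.info("stage=normalize features=%d", len(pset.symbols))

    # --- alias resolution on row symbols ----------------------------------
    if aliases is not None:
        resolved = [aliases.resolve(s) for s in pset.symbols]
        renames = sum(a != b for a, b in zip(pset.symbols, resolved))
        if len(set(resolved)) != len(resolved):
            fail("annotation", "alias_collision",
                 "alias resolution produced duplicate symbols")
        pset = expression.PairedExpressionSet(
            control=pset.control.set_axis(resolved),
            tumor=pset.tumor.set_axis(resolved))
        logger.info("stage=aliases renamed=%d", renames)
        counts["symbols_renamed"] = renames

    gene_rows = [s for s in pset.symbols if s in set(targets.universe)]
    mirna_rows = [s for s in pset.symbols if s not in set(gene_rows)]
    counts["gene_rows"] = len(gene_rows)

    # --- differential expression ------------------------------------------
    try:
        de = diffexpr.differential_expression(pset, fc_cut=config.fc_cut,
                                              fdr_cut=config.fdr_cut)
    except ValueError as err:
        fail("diff_expression", "invalid", str(err))
    de.to_csv(out / "de_table.tsv", sep="\t")
    artifacts.append(out / "de_table.tsv")
    counts["de_up"] = int((de["direction"] == "up").sum())
    counts["de_down"] = int((de["direction"] == "down").sum())
    logger.info("stage=de features=%d up=%d down=%d", len(de),
                counts["de_up"], counts["de_down"])

    # --- per-condition networks -------------------------------------------
    cross_symbols: set[str] = set()
    if config.second_expression:
        try:
            second = expression.load_paired_set(config.second_expression,
                                                config.second_samplesheet)
        except (OSError, ValueError) as err:
            fail("networks", "second_dataset", str(err))
        cross_symbols = set(second.symbols)

    nets = {}
    for condition, values in (("control", pset.control.loc[mirna_rows]),
                              ("tumor", pset.tumor.loc[mirna_rows])):
        net = corrnet.build_network(values, condition, r_cut=config.r_cut,
                                    alpha=config.alpha)
        for symbol, attrs in net.node_attrs.items():
            if symbol in de.index:
                attrs.de_direction = str(de.loc[symbol, "direction"])
            attrs.cross_dataset = symbol in cross_symbols
        corrnet.write_edges_tsv(net, out / f"edges_{condition}.tsv")
        corrnet.write_sif(net, out / f"network_{condition}.sif")
        artifacts += [out / f"edges_{condition}.tsv", out / f"network_{condition}.sif"]
        counts[f"edges_{condition}"] = len(net.edges)
        logger.info("stage=network condition=%s pairs=%d edges=%d", condition,
                    len(mirna_rows) * (len(mirna_rows) - 1) // 2, len(net.edges))
        nets[condition] = net

    # --- partition --------------------------------------------------------
    partition = algebra.partition_networks(nets["tumor"], nets["control"])
    partition.write_json(out / "partition.json")
    artifacts.append(out / "partition.json")
    counts.update(partition.venn_counts)
    logger.info("stage=partition %s", partition.venn_counts)

    # --- clock-controller tagging -----------------------------------------
    for net in nets.values():
        algebra.tag_clock_controllers(net, targets)
        corrnet.write_graphml(net, out / f"network_{net.condition}.graphml")
        artifacts.append(out / f"network_{net.condition}.graphml")
    pair_tags, node_flags = algebra.tag_clock_controllers(partition, targets)
    counts["clock_controller_pairs"] = int(sum(pair_tags.values()))
    counts["clock_targeting_nodes"] = int(sum(node_flags.values()))
    logger.info("stage=annotation clock_pairs=%d clock_nodes=%d",
                counts["clock_controller_pairs"], counts["clock_targeting_nodes"])

    # --- topology ---------------------------------------------------------
    topo = {}
    for condition, net in nets.items():
        frame = topology.network_topology(net)
        frame.to_csv(out / f"topology_{condition}.tsv", sep="\t")
        artifacts.append(out / f"topology_{condition}.tsv")
        topo[condition] = frame
    logger.info("stage=topology nodes_control=%d nodes_tumor=%d",
                len(topo["control"]), len(topo["tumor"]))

    # --- gene-miRNA coupling ----------------------------------------------
    rows = []
    for mirna, gene in targets.pairs():
        match = [s for s in pset.symbols if algebra._norm_mirna(s) == mirna]
        if gene not in gene_rows or not match:
            continue
        msym = match[0]
        for condition, frameset in (("control", pset.control), ("tumor", pset.tumor)):
            try:
                r, p = validation.gene_mirna_correlation(
                    frameset.loc[gene].to_numpy(), frameset.loc[msym].to_numpy())
            except ValueError:
                continue
            rows.append((msym, gene, condition, r, p))
    gm = pd.DataFrame(rows, columns=["mirna", "gene", "condition", "r", "p"])
    gm.to_csv(out / "gene_mirna.tsv", sep="\t", index=False)
    artifacts.append(out / "gene_mirna.tsv")
    counts["gene_mirna_pairs"] = len(gm)

    # --- candidate ranking ------------------------------------------------
    candidates = validation.rank_candidates(de, partition, targets,
                                            topo["control"], topo["tumor"],
                                            weights=config.weights)
    candidates.to_csv(out / "candidates.tsv", sep="\t")
    artifacts.append(out / "candidates.tsv")
    counts["candidates"] = len(candidates)
    logger.info("stage=candidates eligible=%d top=%s", len(candidates),
                candidates.index[0] if len(candidates) else None)

    # --- summary + manifest -----------------------------------------------
    summary = {"counts": counts, "seed": config.seed,
               "thresholds": {"r_cut": config.r_cut, "alpha": config.alpha,
                              "fc_cut": config.fc_cut, "fdr_cut": config.fdr_cut}}
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    artifacts.append(out / "summary.json")
    manifest = {p.name: {"sha256": _sha256(p), "bytes": p.stat().st_size}
                for p in artifacts}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
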