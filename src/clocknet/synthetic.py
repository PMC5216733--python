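"""Synthetic matched tumor/control cohort generator with planted structure.

Every downstream stage of the analysis (paired differential expression,
per-condition Pearson networks, edge partitioning, topology, candidate
ranking) is testable without external data because this module plants a
known truth and emits it alongside the matrices:

* correlation modules — groups of miRNAs sharing a latent factor so that
  every within-module pair has an exact population Pearson correlation rho;
  tumor and control carry independent module lists, so condition-specific
  edge gain/loss and sign flips are planted directly;
* signed log2 fold-changes added to the tumor columns of chosen features;
* miRNA -> gene coupling: an mRNA generated with a stated (typically
  negative) population correlation to its targeting miRNA, per condition.

Matrices are log2 intensities centered at 8.0 (microarray-like).  Module
members are built as sqrt(|rho|)*F + sqrt(1-|rho|)*eps with standard normal
F and eps, giving unit variance and exact pairwise population correlation
rho; features outside any module are N(8, noise_sd^2).  Negative rho is
supported for two-member modules only (loadings +sqrt|rho| / -sqrt|rho|).

One PRNG stream per logical block (control modules, tumor modules,
background, DE, coupling), split from the master seed, so adding a module
leaves every other block's draws untouched.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import PairedExpressionSet, write_paired_set

BASELINE_LOG2 = 8.0


@dataclass(frozen=True)
class Module:
    """A planted correlation module: member symbols plus target pairwise rho."""

    members: tuple[str, ...]
    rho: float

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("a module needs at least 2 members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"duplicate symbol within module {self.members}")
        if not abs(self.rho) < 1:
            raise ValueError(f"|rho| must be < 1, got {self.rho} (rho = ±1 is degenerate)")
        if self.rho < 0 and len(self.members) > 2:
            raise ValueError("negative rho is only attainable for two-member modules")

    def pairs(self):
        return [tuple(sorted(p)) for p in itertools.combinations(self.members, 2)]


@dataclass
class SyntheticConfig:
    """Stated world for one synthetic cohort.

    Defaults emulate a 14-patient matched microarray cohort with a few
    hundred miRNA features.  ``de_effects`` maps a symbol to its additive
    log2 shift in tumor; ``coupling`` lists (mirna, gene, rho) triples
    generating the gene with population correlation rho to its miRNA.
    """

    n_patients: int = 14
    n_mirnas: int = 300
    clock_genes: tuple[str, ...] = ()
    modules_control: tuple[Module, ...] = ()
    modules_tumor: tuple[Module, ...] = ()
    de_effects: dict[str, float] = field(default_factory=dict)
    coupling: tuple[tuple[str, str, float], ...] = ()
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 3:
            raise ValueError("n_patients must be >= 3")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for side in (self.modules_control, self.modules_tumor):
            seen: set[str] = set()
            for mod in side:
                overlap = seen & set(mod.members)
                if overlap:
                    raise ValueError(f"duplicate symbol across modules: {sorted(overlap)}")
                seen |= set(mod.members)
        for m, g, rho in self.coupling:
            if not abs(rho) < 1:
                raise ValueError(f"coupling rho must satisfy |rho| < 1, got {rho}")
            if g in self.module_symbols():
                raise ValueError(f"coupled gene {g!r} may not belong to a miRNA module")

    def module_symbols(self) -> set[str]:
        out: set[str] = set()
        for mod in self.modules_control + self.modules_tumor:
            out |= set(mod.members)
        return out

    def mirna_symbols(self) -> list[str]:
        """All miRNA row symbols, named members first, background fill after."""
        named = sorted(self.module_symbols() | (set(self.de_effects) - self.gene_symbols()) |
                       {m for m, _, _ in self.coupling})
        n_background = self.n_mirnas - len(named)
        if n_background < 0:
            raise ValueError(f"n_mirnas={self.n_mirnas} smaller than {len(named)} named miRNAs")
        width = max(4, len(str(self.n_mirnas)))
        background = [f"hsa-miR-syn{str(i).zfill(width)}" for i in range(1, n_background + 1)]
        return named + background

    def gene_symbols(self) -> set[str]:
        return set(self.clock_genes) | {g for _, g, _ in self.coupling}

    def all_symbols(self) -> list[str]:
        return self.mirna_symbols() + sorted(self.gene_symbols())


@dataclass
class GroundTruth:
    """Planted structure emitted alongside the data, never read by the pipeline."""

    true_edges_control: dict[tuple[str, str], float]
    true_edges_tumor: dict[tuple[str, str], float]
    true_de: dict[str, float]  # symbol -> planted signed fold change
    true_coupling: list[tuple[str, str, float]]

    def to_jsonable(self) -> dict:
        return {
            "true_edges_control": [[a, b, r] for (a, b), r in sorted(self.true_edges_control.items())],
            "true_edges_tumor": [[a, b, r] for (a, b), r in sorted(self.true_edges_tumor.items())],
            "true_de": dict(sorted(self.true_de.items())),
            "true_coupling": [list(t) for t in self.true_coupling],
        }

    @classmethod
    def from_jsonable(cls, obj: dict) -> "GroundTruth":
        return cls(
            true_edges_control={(a, b): r for a, b, r in obj["true_edges_control"]},
            true_edges_tumor={(a, b): r for a, b, r in obj["true_edges_tumor"]},
            true_de=dict(obj["true_de"]),
            true_coupling=[tuple(t) for t in obj["true_coupling"]],
        )


#: fixed spawn order of the per-block PRNG streams split from the master seed
_BLOCKS = ("modules_control", "modules_tumor", "background_control",
           "background_tumor", "coupling_control", "coupling_tumor")


def _streams(seed: int) -> dict[str, np.random.SeedSequence]:
    children = np.random.SeedSequence(seed).spawn(len(_BLOCKS))
    return dict(zip(_BLOCKS, children))


def _condition_matrix(symbols, n, modules, modules_ss, rng_background,
                      noise_sd) -> tuple[pd.DataFrame, dict[str, float]]:
    """One condition's pre-shift matrix plus each symbol's population SD."""
    values = pd.DataFrame(rng_background.normal(0.0, noise_sd, size=(len(symbols), n)),
                          index=symbols, columns=range(n))
    pop_sd = {s: noise_sd for s in symbols}
    # one child stream per module, so adding a module leaves the rest untouched
    module_rngs = [np.random.default_rng(c) for c in modules_ss.spawn(len(modules))] if modules else []
    for mod, rng in zip(modules, module_rngs):
        factor = rng.normal(size=n)
        a = np.sqrt(abs(mod.rho))
        resid = np.sqrt(1.0 - abs(mod.rho))
        loadings = [a] * len(mod.members)
        if mod.rho < 0:
            loadings[1] = -a  # two-member module, checked at construction
        for sym, load in zip(mod.members, loadings):
            values.loc[sym] = load * factor + resid * rng.normal(size=n)
            pop_sd[sym] = 1.0
    return values, pop_sd


def generate_cohort(config: SyntheticConfig) -> tuple[PairedExpressionSet, GroundTruth]:
    """Generate matched control/tumor log2 matrices with the planted truth.

    Deterministic for a fixed config (seed included): the same config yields
    bit-identical matrices.
    """
    streams = _streams(config.seed)
    mirnas = config.mirna_symbols()
    genes = sorted(config.gene_symbols())
    n = config.n_patients
    patients = [f"P{str(i).zfill(2)}" for i in range(1, n + 1)]

    cond = {}
    for key, mods in (("control", config.modules_control), ("tumor", config.modules_tumor)):
        rng_background = np.random.default_rng(streams[f"background_{key}"])
        mat, pop_sd = _condition_matrix(
            mirnas, n, mods, streams[f"modules_{key}"], rng_background, config.noise_sd)
        # gene rows: background unless coupled
        gene_rows = pd.DataFrame(
            rng_background.normal(0.0, config.noise_sd, size=(len(genes), n)),
            index=genes, columns=range(n))
        rng_coupling = np.random.default_rng(streams[f"coupling_{key}"])
        for mirna, gene, rho in config.coupling:
            z = (mat.loc[mirna].to_numpy()) / pop_sd[mirna]  # exact standardization
            eps = rng_coupling.normal(size=n)
            gene_rows.loc[gene] = rho * z + np.sqrt(1.0 - rho ** 2) * eps
        full = pd.concat([mat, gene_rows])
        full.columns = patients
        cond[key] = full + BASELINE_LOG2

    from .diffexpr import signed_fold_change

    for sym, shift in config.de_effects.items():
        if sym not in cond["tumor"].index:
            raise ValueError(f"de_effects symbol {sym!r} not among generated features")
        cond["tumor"].loc[sym] = cond["tumor"].loc[sym] + shift

    pset = PairedExpressionSet(control=cond["control"], tumor=cond["tumor"])
    truth = GroundTruth(
        true_edges_control={p: m.rho for m in config.modules_control for p in m.pairs()},
        true_edges_tumor={p: m.rho for m in config.modules_tumor for p in m.pairs()},
        true_de={s: float(signed_fold_change(shift)) for s, shift in config.de_effects.items()},
        true_coupling=list(config.coupling),
    )
    return pset, truth


def write_fixture(pset: PairedExpressionSet, truth: GroundTruth, out_dir) -> dict:
    """Write expression.tsv, samplesheet.tsv and truth.json plus a manifest.

    The TSVs are the exact dialect consumed by :func:`expression.load_paired_set`;
    the round trip is lossless.  Returns the manifest (also written as
    manifest.json) listing every emitted file with its row/column counts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = write_paired_set(pset, out_dir / "expression.tsv", out_dir / "samplesheet.tsv")
    truth_path = out_dir / "truth.json"
    truth_obj = truth.to_jsonable()
    truth_path.write_text(json.dumps(truth_obj, indent=1, sort_keys=True) + "\n")
    manifest["truth"] = {
        "path": str(truth_path),
        "rows": len(truth_obj["true_edges_control"]) + len(truth_obj["true_edges_tumor"]),
        "cols": 3,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# Study-like stated world
# ---------------------------------------------------------------------------

#: log2 shift whose signed fold change is ~ -6.80, the headline down-regulation
#: of the clock-targeting candidate miRNA.
CANDIDATE_SHIFT_LOG2 = -2.76595

#: planted miRNA -> clock-gene coupling strength (negative regulation).
CANDIDATE_COUPLING_RHO = -0.32


def study_like_config(seed: int = 0, n_mirnas: int = 300,
                      noise_sd: float = 0.3) -> SyntheticConfig:
    """The default stated world: a 14-pair matched microarray-style cohort.

    Plants, in control tissue, a tight (rho 0.95) module around the
    TIMELESS-targeting candidate hsa-miR-139-5p that disappears entirely in
    tumor (the candidate loses all its edges); a module around hsa-let-7e-5p
    that persists in tumor with rewired membership; a sign-flipping pair;
    and a tumor-exclusive module.  DE shifts include the candidate's
    -2.76595 log2 (signed FC ~ -6.80), a moderately down-regulated
    clock-targeting hub, an up-regulated miRNA and an equally deregulated
    non-clock decoy.  TIMELESS mRNA is generated with rho = -0.32 to the
    candidate miRNA in both conditions.
    """
    m139 = "hsa-miR-139-5p"
    let7e = "hsa-let-7e-5p"
    modules_control = (
        Module(("hsa-miR-125b-5p", "hsa-miR-140-3p", "hsa-miR-99b-5p", let7e, m139), 0.95),
        Module(("hsa-miR-20a-5p", "hsa-miR-17-5p", "hsa-miR-106a-5p"), 0.9),
        Module(("hsa-miR-flipA", "hsa-miR-flipB"), 0.9),
    )
    modules_tumor = (
        Module((let7e, "hsa-miR-214-3p", "hsa-miR-212-3p"), 0.9),
        Module(("hsa-miR-20a-5p", "hsa-miR-17-5p", "hsa-miR-106a-5p"), 0.9),
        Module(("hsa-miR-flipA", "hsa-miR-flipB"), -0.9),
        Module(("hsa-miR-19b-3p", "hsa-miR-99b-5p"), -0.9),
    )
    de_effects = {
        m139: CANDIDATE_SHIFT_LOG2,
        let7e: -2.0,
        "hsa-miR-19b-3p": 1.2,
        "hsa-miR-decoy": CANDIDATE_SHIFT_LOG2,
    }
    return SyntheticConfig(
        n_patients=14,
        n_mirnas=n_mirnas,
        clock_genes=("TIMELESS",),
        modules_control=modules_control,
        modules_tumor=modules_tumor,
        de_effects=de_effects,
        coupling=((m139, "TIMELESS", CANDIDATE_COUPLING_RHO),),
        noise_sd=noise_sd,
        seed=seed,
    )
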