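"""Edge-set algebra between condition networks, symbol resolution, clock tags.

Two miRNAs are *coherently correlated* when their pair survives filtering in
both the tumor and the control network with the same correlation sign; such
pairs form the common set.  Pairs surviving in both networks with opposite
signs are kept apart as a fourth, sign-flip category (neither common nor
exclusive), so the four sets are pairwise disjoint and cover the union of
both networks' pairs.

A pair is tagged *clock-controller* when at least one member has a validated
clock-gene target.  miRNA symbols are resolved against a miRBase-style alias
table (rows: accession <tab> alias1;alias2;...;) — the canonical name is the
last alias of the matching row; symbols matching no row or several rows
(e.g. ambiguous between -5p and -3p products) are kept unchanged and logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd

from .corrnet import CorrelationNetwork

logger = logging.getLogger(__name__)

#: Core circadian oscillator gene universe.
CLOCK_GENES = ("ARNTL", "ARNTL2", "CLOCK", "NPAS2", "PER1", "PER2", "PER3",
               "CRY1", "CRY2", "NR1D1", "NR1D2", "RORA", "TIMELESS", "TIPIN",
               "CSNK1E", "SIRT1")

#: miRWalk-validated clock-gene targets of the six clock-targeting miRNAs
#: recurrently deregulated in colorectal tumors.
VALIDATED_CLOCK_TARGETS: dict[str, frozenset[str]] = {
    "hsa-let-7e-5p": frozenset({"PER1", "CLOCK"}),
    "hsa-miR-125b-5p": frozenset({"PER1", "RORA", "TIPIN"}),
    "hsa-miR-140-3p": frozenset({"NPAS2", "TIMELESS"}),
    "hsa-miR-99b-5p": frozenset({"PER1", "RORA", "TIMELESS"}),
    "hsa-miR-19b-3p": frozenset({"TIMELESS", "NR1D2"}),
    "hsa-miR-139-5p": frozenset({"TIMELESS"}),
}

Pair = tuple[str, str]


def _norm_mirna(symbol: str) -> str:
    s = symbol.strip().lower()
    if not s.startswith("hsa-"):
        s = "hsa-" + s
    return s


@dataclass
class EdgePartition:
    """Common / exclusive / sign-flip pair sets from two condition networks."""

    common: set[Pair]
    sign_flip: set[Pair]
    tumor_exclusive: set[Pair]
    control_exclusive: set[Pair]

    @property
    def venn_counts(self) -> dict[str, int]:
        return {
            "common": len(self.common),
            "sign_flip": len(self.sign_flip),
            "tumor_exclusive": len(self.tumor_exclusive),
            "control_exclusive": len(self.control_exclusive),
        }

    def all_pairs(self) -> set[Pair]:
        return self.common | self.sign_flip | self.tumor_exclusive | self.control_exclusive

    def to_jsonable(self) -> dict:
        return {
            "common": sorted(map(list, self.common)),
            "sign_flip": sorted(map(list, self.sign_flip)),
            "tumor_exclusive": sorted(map(list, self.tumor_exclusive)),
            "control_exclusive": sorted(map(list, self.control_exclusive)),
            "venn_counts": self.venn_counts,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_jsonable(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_jsonable(cls, obj: dict) -> "EdgePartition":
        return cls(common={tuple(p) for p in obj["common"]},
                   sign_flip={tuple(p) for p in obj["sign_flip"]},
                   tumor_exclusive={tuple(p) for p in obj["tumor_exclusive"]},
                   control_exclusive={tuple(p) for p in obj["control_exclusive"]})


def partition_signed_pairs(tumor_signs: dict[Pair, str],
                           control_signs: dict[Pair, str]) -> EdgePartition:
    """Partition from raw pair -> sign maps (the set-algebra core)."""
    t_pairs, c_pairs = set(tumor_signs), set(control_signs)
    both = t_pairs & c_pairs
    common = {p for p in both if tumor_signs[p] == control_signs[p]}
    return EdgePartition(
        common=common,
        sign_flip=both - common,
        tumor_exclusive=t_pairs - c_pairs,
        control_exclusive=c_pairs - t_pairs,
    )


def partition_networks(tumor: CorrelationNetwork,
                       control: CorrelationNetwork) -> EdgePartition:
    """Partition the two networks' (post-filter) edge sets.

    Requires both networks to have been built with the same r_cut and alpha.
    """
    if (tumor.r_cut, tumor.alpha) != (control.r_cut, control.alpha):
        raise ValueError(
            f"threshold mismatch: tumor (r_cut={tumor.r_cut}, alpha={tumor.alpha}) "
            f"vs control (r_cut={control.r_cut}, alpha={control.alpha})")
    return partition_signed_pairs(tumor.edge_signs(), control.edge_signs())


# ---------------------------------------------------------------------------
# Alias resolution
# ---------------------------------------------------------------------------

@dataclass
class AliasTable:
    """miRBase aliases.txt dialect: accession <tab> semicolon-separated aliases."""

    rows: list[tuple[str, tuple[str, ...]]]
    _index: dict[str, set[int]] = field(init=False, repr=False)

    def __post_init__(self):
        self._index = {}
        for i, (_, aliases) in enumerate(self.rows):
            if len(set(aliases)) != len(aliases):
                raise ValueError(f"duplicate alias within row {self.rows[i][0]}")
            for alias in aliases:
                self._index.setdefault(_norm_mirna(alias), set()).add(i)

    @classmethod
    def from_file(cls, path) -> "AliasTable":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                accession, _, aliases = line.partition("\t")
                names = tuple(a for a in aliases.split(";") if a)
                if names:
                    rows.append((accession, names))
        return cls(rows=rows)

    def resolve(self, raw: str) -> str:
        """Latest (last-listed) alias of the unique row containing ``raw``.

        Unresolvable symbols — matching no row, or ambiguously matching
        several rows (e.g. both -5p and -3p products) — are returned
        unchanged and logged.
        """
        hits = self._index.get(_norm_mirna(raw), set())
        if len(hits) == 1:
            return self.rows[next(iter(hits))][1][-1]
        if not hits:
            logger.info("symbol %r matches no alias row; kept with its original name", raw)
        else:
            logger.info("symbol %r is ambiguous across %d alias rows; kept with its original name",
                        raw, len(hits))
        return raw


def resolve_symbol(raw: str, aliases: AliasTable) -> str:
    return aliases.resolve(raw)


# ---------------------------------------------------------------------------
# Clock-gene target map
# ---------------------------------------------------------------------------

@dataclass
class TargetMap:
    """miRNA -> validated clock-gene target sets over a configured gene universe."""

    targets: dict[str, frozenset[str]]
    universe: tuple[str, ...] = CLOCK_GENES

    def __post_init__(self):
        allowed = set(self.universe)
        cleaned = {}
        for mirna, genes in self.targets.items():
            genes = frozenset(genes)
            outside = genes - allowed
            if outside:
                raise ValueError(f"{mirna}: targets outside the clock universe: {sorted(outside)}")
            if genes:  # no empty target sets stored
                cleaned[_norm_mirna(mirna)] = genes
        self.targets = cleaned

    @classmethod
    def validated(cls) -> "TargetMap":
        return cls(targets=dict(VALIDATED_CLOCK_TARGETS))

    @classmethod
    def from_tsv(cls, path, universe=CLOCK_GENES) -> "TargetMap":
        """Read one (mirna <tab> gene) interaction per row."""
        frame = pd.read_csv(path, sep="\t", header=None, names=["mirna", "gene"],
                            comment="#", dtype=str)
        targets: dict[str, set[str]] = {}
        for row in frame.itertuples(index=False):
            targets.setdefault(row.mirna, set()).add(row.gene)
        return cls(targets={m: frozenset(g) for m, g in targets.items()}, universe=universe)

    def targets_of(self, symbol: str) -> frozenset[str]:
        return self.targets.get(_norm_mirna(symbol), frozenset())

    def is_clock_targeting(self, symbol: str) -> bool:
        return bool(self.targets_of(symbol))

    def pairs(self) -> list[tuple[str, str]]:
        return sorted((m, g) for m, genes in self.targets.items() for g in genes)


def tag_clock_controllers(obj, targets: TargetMap):
    """Tag clock-controller pairs and flag clock-targeting nodes.

    For a :class:`CorrelationNetwork`, sets ``node_attrs[*].clock_target``
    in place and returns ``{pair: bool}`` over its edges.  For an
    :class:`EdgePartition`, returns ``({pair: bool}, {node: bool})`` over
    the union of all four sets.
    """
    def pair_tag(a, b):
        return bool(targets.targets_of(a) | targets.targets_of(b))

    if isinstance(obj, CorrelationNetwork):
        for symbol, attrs in obj.node_attrs.items():
            attrs.clock_target = targets.is_clock_targeting(symbol)
        return {pair: pair_tag(*pair) for pair in obj.edges}
    if isinstance(obj, EdgePartition):
        pairs = obj.all_pairs()
        nodes = {s for pair in pairs for s in pair}
        return ({pair: pair_tag(*pair) for pair in pairs},
                {s: targets.is_clock_targeting(s) for s in nodes})
    raise TypeError(f"cannot tag object of type {type(obj).__name__}")
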