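"""Per-condition miRNA-miRNA Pearson correlation networks.

An edge joins two features when the Pearson coefficient over complete
observation pairs satisfies |r| >= r_cut and its two-sided p <= alpha.  The
p value comes from the exact small-sample t transform
t = r*sqrt(n-2)/sqrt(1-r^2), df = n-2 (|r| = 1 maps to p = 0).  The main
analysis threshold is |r| >= 0.8; a 0.6 preset mirrors the broader screen.
Edge p values are left uncorrected by default (the filtering rule is raw
p <= 0.05); an optional BH mode adjusts them before filtering.

Pairs are keyed canonically (lexicographically sorted symbols) so that
edge-set algebra across conditions is well defined.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import benjamini_hochberg

R_CUT_MAIN = 0.8
R_CUT_BROAD = 0.6
MIN_PAIRS = 5


@dataclass
class NodeAttrs:
    de_direction: str = "ns"
    clock_target: bool = False
    cross_dataset: bool = False


@dataclass(frozen=True)
class CorrelationEdge:
    """One significant correlation between a canonical (a < b) symbol pair."""

    a: str
    b: str
    r: float
    p: float
    n_used: int

    def __post_init__(self):
        if not self.a < self.b:
            raise ValueError(f"edge pair not canonical: {(self.a, self.b)}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b)

    @property
    def sign(self) -> str:
        return "+" if self.r >= 0 else "-"


@dataclass
class CorrelationNetwork:
    condition: str
    r_cut: float
    alpha: float
    edges: dict[tuple[str, str], CorrelationEdge] = field(default_factory=dict)
    node_attrs: dict[str, NodeAttrs] = field(default_factory=dict)
    skipped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for (a, b) in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            for s in (a, b):
                self.node_attrs.setdefault(s, NodeAttrs())

    @property
    def nodes(self) -> list[str]:
        return list(self.node_attrs)

    def degree(self, symbol: str) -> int:
        return sum(symbol in pair for pair in self.edges)

    def neighbors(self, symbol: str) -> set[str]:
        out = set()
        for a, b in self.edges:
            if a == symbol:
                out.add(b)
            elif b == symbol:
                out.add(a)
        return out

    def edge_signs(self) -> dict[tuple[str, str], str]:
        return {pair: e.sign for pair, e in self.edges.items()}


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise ValueError(f"self-pair {a!r}")
    return (a, b) if a < b else (b, a)


def p_from_r(r, n):
    """Two-sided p for Pearson r via the exact t transform, df = n - 2."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r ** 2)
        p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(n - 2, 1))
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.minimum(p, 1.0)
    return p if p.ndim else float(p)


def pearson(x, y) -> tuple[float, float, int]:
    """Pearson r, two-sided p and the complete-pair count for two vectors.

    Missing values are removed pairwise; fewer than 5 complete pairs or a
    constant vector raises ValueError.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < MIN_PAIRS:
        raise ValueError(f"need >= {MIN_PAIRS} complete pairs, got {n}")
    dx = x - x.mean()
    dy = y - y.mean()
    den = np.sqrt((dx ** 2).sum() * (dy ** 2).sum())
    if den == 0.0:
        raise ValueError("constant vector: correlation undefined")
    r = float(np.clip((dx * dy).sum() / den, -1.0, 1.0))
    return r, p_from_r(r, n), n


def build_network(values: pd.DataFrame, condition: str, r_cut: float = R_CUT_MAIN,
                  alpha: float = 0.05, min_n: int = MIN_PAIRS,
                  p_adjust: str = "none") -> CorrelationNetwork:
    """Correlation network over all feature pairs of one condition's matrix.

    ``values`` is features x samples.  Every unordered pair is evaluated
    (pairwise-complete observations); an edge is kept iff |r| >= r_cut and
    p <= alpha (p optionally BH-adjusted across all evaluated pairs).
    Constant features and pairs with fewer than ``min_n`` complete
    observations are skipped, with counts recorded.
    """
    if not 0.0 < r_cut < 1.0:
        raise ValueError(f"r_cut must lie in (0, 1), got {r_cut}")
    if p_adjust not in ("none", "bh"):
        raise ValueError(f"p_adjust must be 'none' or 'bh', got {p_adjust!r}")
    symbols = list(values.index)
    rmat = values.T.corr(min_periods=min_n).to_numpy()
    finite = np.isfinite(values.to_numpy()).astype(np.int64)
    nmat = finite @ finite.T
    with np.errstate(invalid="ignore"):
        pmat = p_from_r(rmat, nmat)

    iu, ju = np.triu_indices(len(symbols), k=1)
    r_u, p_u, n_u = rmat[iu, ju], np.asarray(pmat)[iu, ju], nmat[iu, ju]
    evaluable = np.isfinite(r_u) & (n_u >= min_n)
    skipped = {
        "too_few_pairs": int((n_u < min_n).sum()),
        "constant_feature": int((~np.isfinite(r_u) & (n_u >= min_n)).sum()),
    }
    if p_adjust == "bh":
        adj = np.full(p_u.shape, np.nan)
        adj[evaluable] = benjamini_hochberg(p_u[evaluable])
        p_u = adj

    keep = evaluable & (np.abs(r_u) >= r_cut) & (p_u <= alpha)
    edges = {}
    for i, j, r, p, n in zip(iu[keep], ju[keep], r_u[keep], p_u[keep], n_u[keep]):
        pair = canonical_pair(symbols[i], symbols[j])
        edges[pair] = CorrelationEdge(pair[0], pair[1], float(np.clip(r, -1, 1)),
                                      float(p), int(n))
    net = CorrelationNetwork(condition=condition, r_cut=r_cut, alpha=alpha,
                             edges=edges, skipped=skipped)
    for s in symbols:
        net.node_attrs.setdefault(s, NodeAttrs())
    return net


def correlation_table(values: pd.DataFrame, min_n: int = MIN_PAIRS) -> pd.DataFrame:
    """Full unfiltered pair table (symbol_a, symbol_b, r, p, n_used), for inspection."""
    symbols = list(values.index)
    rmat = values.T.corr(min_periods=min_n).to_numpy()
    finite = np.isfinite(values.to_numpy()).astype(np.int64)
    nmat = finite @ finite.T
    pmat = np.asarray(p_from_r(rmat, nmat))
    iu, ju = np.triu_indices(len(symbols), k=1)
    rows = []
    for i, j in zip(iu, ju):
        a, b = canonical_pair(symbols[i], symbols[j])
        rows.append((a, b, rmat[i, j], pmat[i, j], int(nmat[i, j])))
    return pd.DataFrame(rows, columns=["symbol_a", "symbol_b", "r", "p", "n_used"])


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def edges_frame(net: CorrelationNetwork) -> pd.DataFrame:
    rows = [(e.a, e.b, e.r, e.p, e.n_used, e.sign, net.condition)
            for e in net.edges.values()]
    frame = pd.DataFrame(rows, columns=["symbol_a", "symbol_b", "r", "p",
                                        "n_used", "sign", "condition"])
    return frame.sort_values(["symbol_a", "symbol_b"]).reset_index(drop=True)


def write_edges_tsv(net: CorrelationNetwork, path) -> None:
    edges_frame(net).to_csv(path, sep="\t", index=False)


def read_edges_tsv(path) -> CorrelationNetwork:
    frame = pd.read_csv(path, sep="\t")
    edges = {}
    condition = str(frame["condition"].iloc[0]) if len(frame) else "unknown"
    for row in frame.itertuples(index=False):
        pair = canonical_pair(row.symbol_a, row.symbol_b)
        edges[pair] = CorrelationEdge(pair[0], pair[1], float(row.r),
                                      float(row.p), int(row.n_used))
    return CorrelationNetwork(condition=condition, r_cut=np.nan, alpha=np.nan,
                              edges=edges)


def write_sif(net: CorrelationNetwork, path) -> None:
    """Simple interaction format: symbol_a <tab> corr <tab> symbol_b."""
    with open(path, "w") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\tcorr\t{b}\n")


def write_graphml(net: CorrelationNetwork, path) -> None:
    """GraphML with r/p/sign edge attributes and the node attribute flags."""
    root = ET.Element("graphml", xmlns="http://graphml.graphdrawing.org/xmlns")
    keys = [("d_r", "edge", "r", "double"), ("d_p", "edge", "p", "double"),
            ("d_sign", "edge", "sign", "string"),
            ("d_de", "node", "de_direction", "string"),
            ("d_clock", "node", "clock_target", "boolean"),
            ("d_cross", "node", "cross_dataset", "boolean")]
    for kid, domain, name, typ in keys:
        ET.SubElement(root, "key", id=kid, **{"for": domain,
                      "attr.name": name, "attr.type": typ})
    graph = ET.SubElement(root, "graph", id=net.condition, edgedefault="undirected")
    for symbol in sorted(net.node_attrs):
        attrs = net.node_attrs[symbol]
        node = ET.SubElement(graph, "node", id=symbol)
        for kid, value in (("d_de", attrs.de_direction),
                           ("d_clock", str(attrs.clock_target).lower()),
                           ("d_cross", str(attrs.cross_dataset).lower())):
            data = ET.SubElement(node, "data", key=kid)
            data.text = value
    for (a, b), e in sorted(net.edges.items()):
        edge = ET.SubElement(graph, "edge", source=a, target=b)
        for kid, value in (("d_r", repr(e.r)), ("d_p", repr(e.p)), ("d_sign", e.sign)):
            data = ET.SubElement(edge, "data", key=kid)
            data.text = value
    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")
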