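"""Candidate miRNA ranking and small validation statistics.

The ranking makes the qualitative selection of a clock-targeting candidate
("expression levels plus topological considerations") explicit and tunable:
a miRNA is *eligible* when it targets at least one clock gene and is
differentially expressed; its score is

    score = w1 * |log2FC| + w2 * lost_edge_fraction + w3 * hub_delta

where lost_edge_fraction is the fraction of the node's control-network edges
absent from the tumor network and hub_delta the absolute change in degree
centrality between conditions.  Default weights (1, 1, 1) are arbitrary;
multiplying all weights by a positive constant leaves the ranking unchanged.
Ties break by |log2FC|, then symbol.

Also here: the gene-miRNA inverse-correlation test, 2^-ddCt relative
quantification (both the reference convention ddCt = dCt(calibrator) -
dCt(target) and the Livak convention, which are exact reciprocals),
median-split chi-squared association, and Bethesda-panel MSI classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .algebra import EdgePartition, TargetMap
from .corrnet import pearson


@dataclass
class CandidateScore:
    symbol: str
    eligible: bool
    abs_log2fc: float
    lost_edge_fraction: float
    hub_delta: float
    score: float
    rank: int


def _node_degrees(pairs) -> dict[str, int]:
    deg: dict[str, int] = {}
    for a, b in pairs:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    return deg


def rank_candidates(de_table: pd.DataFrame, partition: EdgePartition,
                    targets: TargetMap, topo_control: pd.DataFrame,
                    topo_tumor: pd.DataFrame,
                    weights=(1.0, 1.0, 1.0)) -> pd.DataFrame:
    """Ranked candidate table over eligible (clock-targeting, DE) miRNAs.

    ``topo_control`` / ``topo_tumor`` are topology frames indexed by node
    with a ``degree_centrality`` column; a symbol absent from a network
    contributes 0 there.  Returns a frame indexed by symbol with columns
    eligible through rank, sorted by rank; empty when nothing is eligible.
    """
    weights = tuple(float(w) for w in weights)
    if len(weights) != 3 or any(w < 0 for w in weights):
        raise ValueError(f"weights must be 3 nonnegative numbers, got {weights}")
    w1, w2, w3 = weights

    control_pairs = partition.common | partition.sign_flip | partition.control_exclusive
    control_deg = _node_degrees(control_pairs)
    lost_deg = _node_degrees(partition.control_exclusive)

    rows = []
    for symbol, rec in de_table.iterrows():
        if rec["direction"] == "ns" or not targets.is_clock_targeting(symbol):
            continue
        abs_fc = abs(float(rec["mean_log2_diff"]))
        cdeg = control_deg.get(symbol, 0)
        lost = lost_deg.get(symbol, 0) / cdeg if cdeg else 0.0
        dc_c = float(topo_control["degree_centrality"].get(symbol, 0.0))
        dc_t = float(topo_tumor["degree_centrality"].get(symbol, 0.0))
        hub_delta = abs(dc_c - dc_t)
        score = w1 * abs_fc + w2 * lost + w3 * hub_delta
        rows.append((symbol, True, abs_fc, lost, hub_delta, score))

    frame = pd.DataFrame(rows, columns=["symbol", "eligible", "abs_log2fc",
                                        "lost_edge_fraction", "hub_delta", "score"])
    frame = frame.sort_values(["score", "abs_log2fc", "symbol"],
                              ascending=[False, False, True], kind="mergesort")
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame.set_index("symbol")


def gene_mirna_correlation(gene_values, mirna_values) -> tuple[float, float]:
    """Pearson r and two-sided p between a gene's and a miRNA's expression."""
    r, p, _ = pearson(gene_values, mirna_values)
    return r, p


# ---------------------------------------------------------------------------
# qPCR relative quantification
# ---------------------------------------------------------------------------

@dataclass
class QpcrRecord:
    sample: str
    ct_target: float
    ct_reference: float

    def __post_init__(self):
        for name, ct in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not 0.0 < ct < 45.0:
                raise ValueError(f"{name} must lie in (0, 45), got {ct}")


def delta_ct(records) -> float:
    """dCt = mean(target Ct) - mean(reference Ct) over a sample group."""
    targets = [r.ct_target for r in records]
    refs = [r.ct_reference for r in records]
    if not targets:
        raise ValueError("no qPCR records")
    return float(np.mean(targets) - np.mean(refs))


def ddct(delta_ct_calibrator: float, delta_ct_target: float,
         convention: str = "reciprocal") -> float:
    """Relative quantity 2^-ddCt.

    ``reciprocal`` uses ddCt = dCt(calibrator) - dCt(target), the reciprocal
    of the usual Livak quantity; ``livak`` uses ddCt = dCt(target) -
    dCt(calibrator).  The two are exact reciprocals for every input.
    """
    if convention == "reciprocal":
        exponent = delta_ct_calibrator - delta_ct_target
    elif convention == "livak":
        exponent = delta_ct_target - delta_ct_calibrator
    else:
        raise ValueError(f"convention must be 'reciprocal' or 'livak', got {convention!r}")
    return float(2.0 ** (-exponent))


def ct_ratio(ct_reference: float, ct_target: float) -> float:
    """Reference-Ct / target-Ct ratio, an alternative per-sample readout."""
    if ct_target == 0:
        raise ValueError("target Ct must be nonzero")
    return float(ct_reference / ct_target)


# ---------------------------------------------------------------------------
# Median-split association
# ---------------------------------------------------------------------------

def median_split_association(values, phenotype_labels, yates: bool = False):
    """Median split of expression values vs a categorical phenotype.

    Subjects with value <= median go to the ``low`` group (ties are
    conservative for the high-expression group), the rest to ``high``.
    Association is Pearson's chi-squared without continuity correction
    (``yates=True`` enables it), df = (rows-1)(cols-1).  Returns
    (contingency DataFrame, chi2, p, low_expected_flag); the flag marks any
    expected count < 5.
    """
    values = np.asarray(values, dtype=float)
    labels = pd.Series(list(phenotype_labels))
    if values.size != len(labels):
        raise ValueError("values and phenotype_labels must have equal length")
    if values.size < 4:
        raise ValueError("need at least 4 subjects")
    categories = labels.unique()
    if len(categories) < 2:
        raise ValueError("need at least 2 phenotype categories")
    median = float(np.median(values))
    group = np.where(values <= median, "low", "high")
    table = pd.crosstab(pd.Series(group, name="expression"), labels.rename("phenotype"))
    table = table.reindex(index=["low", "high"], fill_value=0)
    if (table.sum(axis=1) == 0).any():
        raise ValueError("median split produced an empty expression group")
    chi2, p, _, expected = stats.chi2_contingency(table.to_numpy(),
                                                  correction=yates)
    return table, float(chi2), float(p), bool((expected < 5).any())


# ---------------------------------------------------------------------------
# Microsatellite instability
# ---------------------------------------------------------------------------

MSI_PANEL_SIZE = 5


@dataclass
class MsiCall:
    markers_unstable: int
    call: str
    rule_interpolated: bool  # counts 1 and 3 are not stated anchors


def msi_classify(markers_unstable: int) -> MsiCall:
    """Bethesda 5-marker panel call: >=4 MSI-H, 1-3 MSI-L, 0 MSS."""
    k = int(markers_unstable)
    if not 0 <= k <= MSI_PANEL_SIZE:
        raise ValueError(f"markers_unstable must lie in [0, {MSI_PANEL_SIZE}], got {markers_unstable}")
    if k >= 4:
        call = "MSI-H"
    elif k >= 1:
        call = "MSI-L"
    else:
        call = "MSS"
    return MsiCall(markers_unstable=k, call=call, rule_interpolated=k in (1, 3))
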