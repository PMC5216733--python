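"""Paired differential expression with signed fold change and BH FDR.

For each feature the per-patient log2 difference d_i = tumor_i - control_i
is tested with a paired t statistic t = mean(d) / (sd(d)/sqrt(n)), df = n-1,
two-sided p.  The linear fold change uses the signed-ratio convention common
in microarray reports: 2^mean_log2_diff when up, -2^(-mean_log2_diff) when
down, so |signed_fc| >= 1 always and down-regulation is negative.  A feature
is called differentially expressed when |signed_fc| >= 1.5 and its
Benjamini-Hochberg FDR is <= 0.05 (both cutoffs configurable).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .expression import PairedExpressionSet

DE_COLUMNS = ["mean_log2_diff", "signed_fc", "t", "p", "fdr", "direction",
              "n_pairs", "degenerate"]


def signed_fold_change(mean_log2_diff):
    """Signed linear fold change: 1.0 -> +2.0, 0.0 -> +1.0, -2.76595 -> ~ -6.80."""
    x = np.asarray(mean_log2_diff, dtype=float)
    out = np.where(x >= 0, np.exp2(x), -np.exp2(-x))
    return out if out.ndim else float(out)


def _paired_t_from_diffs(d: np.ndarray) -> tuple[float, float, float, int, bool]:
    """(mean, t, p, n_used, degenerate) from complete per-patient differences."""
    d = np.asarray(d, dtype=float)
    d = d[np.isfinite(d)]
    n = d.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    # numerically-zero spread (identical diffs up to float error) is degenerate
    if sd <= 1e-12 * max(1.0, float(np.abs(d).max())):
        if mean == 0.0:
            return 0.0, 0.0, 1.0, n, False
        # zero variance with nonzero mean: infinitely significant, flagged
        return mean, float(np.sign(mean)) * np.inf, 0.0, n, True
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return mean, float(t), min(p, 1.0), n, False


def paired_t(pset: PairedExpressionSet, symbol: str) -> tuple[float, float, float]:
    """Paired t test for one feature; returns (mean_log2_diff, t, p)."""
    d = (pset.tumor.loc[symbol] - pset.control.loc[symbol]).to_numpy()
    mean, t, p, _, _ = _paired_t_from_diffs(d)
    return mean, t, p


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order.

    adjusted_(i) = min over j >= i of p_(j) * m / j, clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.empty(0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def de_filter(records: pd.DataFrame, fc_cut: float = 1.5,
              fdr_cut: float = 0.05) -> pd.DataFrame:
    """Set the DE direction: up / down when the fold-change and FDR cuts pass."""
    out = records.copy()
    up = (out["signed_fc"] >= fc_cut) & (out["fdr"] <= fdr_cut)
    down = (out["signed_fc"] <= -fc_cut) & (out["fdr"] <= fdr_cut)
    out["direction"] = np.where(up, "up", np.where(down, "down", "ns"))
    return out


def differential_expression(pset: PairedExpressionSet, fc_cut: float = 1.5,
                            fdr_cut: float = 0.05) -> pd.DataFrame:
    """Full per-feature paired DE table, indexed by symbol.

    Columns: mean_log2_diff, signed_fc, t, p, fdr, direction, n_pairs,
    degenerate.  Features with fewer than 3 complete pairs are skipped with
    a warning.
    """
    rows, index, skipped = [], [], []
    diffs = pset.diffs()
    for symbol in pset.symbols:
        d = diffs.loc[symbol].to_numpy()
        try:
            mean, t, p, n, degen = _paired_t_from_diffs(d)
        except ValueError:
            skipped.append(symbol)
            continue
        rows.append((mean, t, p, n, degen))
        index.append(symbol)
    if skipped:
        warnings.warn(f"skipped {len(skipped)} features with < 3 complete pairs "
                      f"(first: {skipped[0]!r})")
    if not rows:
        raise ValueError("no feature had >= 3 complete pairs")
    table = pd.DataFrame(rows, index=pd.Index(index, name="symbol"),
                         columns=["mean_log2_diff", "t", "p", "n_pairs", "degenerate"])
    table["signed_fc"] = signed_fold_change(table["mean_log2_diff"].to_numpy())
    table["fdr"] = benjamini_hochberg(table["p"].to_numpy())
    table = de_filter(table, fc_cut=fc_cut, fdr_cut=fdr_cut)
    return table[DE_COLUMNS]


def write_de_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")
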