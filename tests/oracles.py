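"""Independent brute-force oracles used only by the tests.

Everything here is deliberately naive and shares no code path with the
package: shortest paths by exhaustive simple-path enumeration (DFS), the BH
step-up rule as a literal loop, and the edge partition as a per-pair case
analysis.
"""

from __future__ import annotations

import math


def all_simple_paths(adj: dict, s, t) -> list[list]:
    """Every simple path from s to t, by DFS."""
    out = []
    stack = [(s, [s])]
    while stack:
        v, path = stack.pop()
        if v == t:
            out.append(path)
            continue
        for w in adj[v]:
            if w not in path:
                stack.append((w, path + [w]))
    return out


def brute_force_metrics(adj: dict) -> dict:
    """The seven indices by exhaustive path enumeration (graphs of order <= ~8).

    Same stated conventions as the package (component-wise normalization,
    degree centrality over the full graph order, singleton/two-node
    conventions) but computed from enumerated simple paths, never BFS.
    """
    nodes = list(adj)
    n = len(nodes)

    paths = {}   # (s, t) -> list of shortest paths
    dist = {}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            ps = all_simple_paths(adj, s, t)
            if not ps:
                continue
            d = min(len(p) - 1 for p in ps)
            paths[(s, t)] = [p for p in ps if len(p) - 1 == d]
            dist[(s, t)] = dist[(t, s)] = d

    # components from reachability
    comp_of = {}
    for v in nodes:
        comp = frozenset([v] + [w for w in nodes if (v, w) in dist or (w, v) in dist])
        comp_of[v] = comp

    out = {}
    for v in nodes:
        comp = comp_of[v]
        nc = len(comp)
        k = len(adj[v])
        dists_v = [dist[(v, w)] for w in comp if w != v]
        dsum = sum(dists_v)
        aspl = dsum / (nc - 1) if nc > 1 else 0.0
        closeness = (nc - 1) / dsum if dsum > 0 else 0.0
        diameter = max((dist[(a, b)] for a in comp for b in comp if (a, b) in dist),
                       default=0)
        radiality = (diameter + 1 - aspl) / diameter if diameter >= 1 else 1.0
        if nc >= 3:
            raw = 0.0
            for (s, t), sps in paths.items():
                if v in (s, t) or s not in comp:
                    continue
                through = sum(1 for p in sps if v in p[1:-1])
                raw += through / len(sps)
            betweenness = raw / ((nc - 1) * (nc - 2) / 2)
        else:
            betweenness = 0.0
        if k >= 2:
            nbrs = adj[v]
            e_n = sum(1 for a in nbrs for b in adj[a] if b in nbrs) // 2
            clustering = 2 * e_n / (k * (k - 1))
        else:
            clustering = 0.0
        out[v] = {
            "degree": k,
            "degree_centrality": k / (n - 1) if n > 1 else 0.0,
            "betweenness": betweenness,
            "closeness": closeness,
            "clustering_coeff": clustering,
            "radiality": radiality,
            "aspl": aspl,
        }
    return out


def bh_step_up(p_values) -> list:
    """Literal BH step-up: adjusted_(i) = min_{j>=i} p_(j) * m / j, clip 1."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [None] * m
    running = math.inf
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, p_values[i] * m / (pos + 1))
        adjusted[i] = min(running, 1.0)
    return adjusted


def partition_reference(tumor_signs: dict, control_signs: dict) -> dict:
    """Per-pair case analysis over the union of both signed edge sets."""
    out = {"common": set(), "sign_flip": set(), "tumor_exclusive": set(),
           "control_exclusive": set()}
    for pair in set(tumor_signs) | set(control_signs):
        in_t, in_c = pair in tumor_signs, pair in control_signs
        if in_t and in_c:
            if tumor_signs[pair] == control_signs[pair]:
                out["common"].add(pair)
            else:
                out["sign_flip"].add(pair)
        elif in_t:
            out["tumor_exclusive"].add(pair)
        else:
            out["control_exclusive"].add(pair)
    return out
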