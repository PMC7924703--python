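"""Independent brute-force reference implementations used only by tests.

These are deliberately naive: plain Python loops that restate each
definition directly, kept free of any code shared with the package so they
can serve as oracles.
"""

from __future__ import annotations

import numpy as np


def brute_anchor_chain(x, W, upper=True):
    """Naive steepest-secant anchor chain (per-anchor scan, ties -> farthest)."""
    x = list(map(float, x))
    n = len(x)
    anchors = [0]
    a = 0
    while a < n - 1:
        best_j, best_slope = None, None
        for j in range(a + 1, min(a + W, n - 1) + 1):
            slope = (x[j] - x[a]) / (j - a)
            if not upper:
                slope = -slope
            if best_slope is None or slope > best_slope or slope == best_slope:
                # ties broken toward the farthest j (>= keeps the last max)
                if best_slope is None or slope >= best_slope:
                    best_j, best_slope = j, slope
        a = best_j
        anchors.append(a)
    return anchors


def brute_envelope(x, W, upper=True):
    anchors = brute_anchor_chain(x, W, upper)
    xs = np.asarray(anchors, dtype=float)
    ys = np.asarray([x[a] for a in anchors], dtype=float)
    return np.interp(np.arange(len(x)), xs, ys), anchors


def brute_select_candidates(F, s):
    """Three-stage candidate rule, coded as three separate literal passes."""
    F = list(map(float, F))
    n = len(F)
    # stage 1: samples lower than the sample s further
    marked = [i for i in range(n - s) if F[i] < F[i + s]]
    marked_set = set(marked)
    # stage 2: maximal runs of consecutive marked samples, length > s
    runs = []
    for i in marked:
        if i - 1 not in marked_set:
            j = i
            while j + 1 in marked_set:
                j += 1
            if j - i + 1 > s:
                runs.append((i, j))
    # stage 3: max of F in [last, last+s]
    out = []
    for _, last in runs:
        hi = min(last + s, n - 1)
        best = last
        for k in range(last, hi + 1):
            if F[k] > F[best]:
                best = k
        out.append(best)
    return sorted(set(out))


def brute_max_matching(ref, test, tol):
    """Maximum bipartite matching cardinality via networkx Hopcroft–Karp."""
    import networkx as nx

    g = nx.Graph()
    rnodes = [("r", i) for i in range(len(ref))]
    tnodes = [("t", j) for j in range(len(test))]
    g.add_nodes_from(rnodes, bipartite=0)
    g.add_nodes_from(tnodes, bipartite=1)
    for i, r in enumerate(ref):
        for j, t in enumerate(test):
            if abs(t - r) <= tol:
                g.add_edge(("r", i), ("t", j))
    match = nx.bipartite.maximum_matching(g, top_nodes=rnodes)
    return sum(1 for k in match if k[0] == "r")
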