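"""Independent brute-force shortest-path oracle for cost-distance checks.

Builds the 8-connected weighted graph by explicit edge enumeration in pure
Python and runs networkx Dijkstra on it — deliberately sharing no code with
the package's sparse-matrix implementation.
"""

from math import sqrt

import networkx as nx
import numpy as np

EIGHT_NEIGHBOURS = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]


def enumerate_graph(resistance: np.ndarray) -> nx.Graph:
    nrows, ncols = resistance.shape
    g = nx.Graph()
    for r in range(nrows):
        for c in range(ncols):
            if not np.isfinite(resistance[r, c]):
                continue
            g.add_node((r, c))
            for dr, dc in EIGHT_NEIGHBOURS:
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrows and 0 <= cc < ncols and np.isfinite(resistance[rr, cc]):
                    length = sqrt(2.0) if dr != 0 and dc != 0 else 1.0
                    w = 0.5 * (resistance[r, c] + resistance[rr, cc]) * length
                    g.add_edge((r, c), (rr, cc), weight=w)
    return g


def oracle_cost_distance(resistance: np.ndarray, sources) -> np.ndarray:
    """Minimum accumulated cost from any source to every cell (inf if
    unreached), via networkx multi-source Dijkstra."""
    g = enumerate_graph(resistance)
    acc = np.full(resistance.shape, np.inf)
    srcs = [tuple(s) for s in sources if g.has_node(tuple(s))]
    if not srcs:
        return acc
    dist = nx.multi_source_dijkstra_path_length(g, srcs, weight="weight")
    for (r, c), d in dist.items():
        acc[r, c] = d
    return acc
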