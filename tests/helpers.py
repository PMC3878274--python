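"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: the pruning
likelihood is re-derived by exhaustive enumeration over internal-state
assignments, and disparity by direct pair enumeration.
"""

import itertools
import math

import numpy as np

from riskevo.mk_models import transition_matrix_er


def brute_force_loglik(tree, states: dict, q: float, k: int = 4) -> float:
    """Tree likelihood by summing over every internal-state assignment."""
    internal = tree.internal_indices()
    tipstate = {v: states[tree.labels[v]] - 1 for v in tree.tip_indices()}
    P = {v: transition_matrix_er(q, tree.branch_lengths[v], k)
         for v in range(tree.n_nodes) if v != tree.root}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        amap = dict(zip(internal, assign))
        p = 1.0 / k
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            sv = tipstate.get(v, amap.get(v))
            p *= P[v][amap[tree.parent[v]], sv]
        total += p
    return math.log(total) if total > 0 else float("-inf")


def pairwise_disparity(values, metric: str = "avg_sq") -> float:
    """Mean pairwise distance by direct enumeration of unordered pairs."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        return 0.0
    acc, npairs = 0.0, 0
    for i in range(x.size):
        for j in range(i + 1, x.size):
            d = x[i] - x[j]
            acc += d * d if metric == "avg_sq" else abs(d)
            npairs += 1
    return acc / npairs
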