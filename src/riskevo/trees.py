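"""Rooted phylogenies: I/O, consensus, penalized-likelihood dating, time utilities.

The package-wide tree container is :class:`Phylogeny`, a light array-backed
rooted tree with branch lengths in time units.  Newick/Nexus parsing is
delegated to dendropy; everything downstream (depths, relative times,
consensus, dating) operates on the array representation, which is what the
likelihood and simulation code needs anyway.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit


class TreeError(ValueError):
    """Raised for malformed or inconsistent tree input."""


class Phylogeny:
    """Rooted tree with branch lengths.

    Nodes are integers ``0 .. n_nodes-1`` with the root at index 0 (an
    invariant of the constructors here).  ``parent[i]`` is -1 for the root;
    ``branch_lengths[i]`` is the length of the edge above node ``i`` (0 for
    the root).  Tips carry non-empty unique string labels; internal nodes
    have ``None``.
    """

    __slots__ = ("parent", "branch_lengths", "labels", "children", "root")

    def __init__(self, parent, branch_lengths, labels):
        self.parent = np.asarray(parent, dtype=int)
        self.branch_lengths = np.asarray(branch_lengths, dtype=float)
        self.labels = list(labels)
        n = len(self.parent)
        if not (len(self.branch_lengths) == len(self.labels) == n):
            raise TreeError("parent, branch_lengths and labels must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        if not np.all(np.isfinite(self.branch_lengths)):
            raise TreeError("branch lengths must be finite")
        if np.any(self.branch_lengths < 0):
            raise TreeError("branch lengths must be >= 0")
        tips = [self.labels[i] for i in self.tip_indices()]
        if any(lab is None or lab == "" for lab in tips):
            raise TreeError("every tip must carry a non-empty label")
        if len(set(tips)) != len(tips):
            dups = sorted({t for t in tips if tips.count(t) > 1})
            raise TreeError(f"duplicate tip labels: {dups}")
        self._check_connected()

    # -- structure ---------------------------------------------------------

    def _check_connected(self):
        seen = np.zeros(self.n_nodes, dtype=bool)
        stack = [self.root]
        while stack:
            v = stack.pop()
            seen[v] = True
            stack.extend(self.children[v])
        if not seen.all():
            raise TreeError("tree is not connected (orphan nodes present)")

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def tip_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    def internal_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.children[i]]

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices())

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices()]

    def postorder(self) -> list[int]:
        """Children before parents; root last."""
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        return list(reversed(self.postorder()))

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), self.branch_lengths.copy(), list(self.labels))

    def clade_tipsets(self) -> dict[int, frozenset[str]]:
        """Tip-label set descending from every node."""
        sets: dict[int, frozenset[str]] = {}
        for v in self.postorder():
            if not self.children[v]:
                sets[v] = frozenset([self.labels[v]])
            else:
                s = frozenset()
                for c in self.children[v]:
                    s |= sets[c]
                sets[v] = s
        return sets

    # -- depths & times ----------------------------------------------------

    def node_depths(self) -> np.ndarray:
        """Depth (time from the root) of every node; depth(root) = 0."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder():
            if v != self.root:
                d[v] = d[self.parent[v]] + self.branch_lengths[v]
        return d

    def max_depth(self) -> float:
        d = self.node_depths()
        return float(max(d[i] for i in self.tip_indices()))

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = self.node_depths()
        tips = [d[i] for i in self.tip_indices()]
        return (max(tips) - min(tips)) <= tol * max(max(tips), 1.0)

    def relative_times(self, tol: float = 1e-6) -> np.ndarray:
        """Node times on [0, 1]: 0 at the root, 1 at the present (tips).

        Requires an ultrametric tree; raises otherwise.
        """
        if not self.is_ultrametric(tol):
            raise TreeError("relative times require an ultrametric tree")
        d = self.node_depths()
        depth = self.max_depth()
        if depth <= 0:
            raise TreeError("tree has zero depth")
        t = d / depth
        for i in self.tip_indices():
            t[i] = 1.0
        return t

    def rescaled_to_depth(self, depth: float = 1.0) -> "Phylogeny":
        cur = self.max_depth()
        if cur <= 0:
            raise TreeError("cannot rescale a zero-depth tree")
        out = self.copy()
        out.branch_lengths *= depth / cur
        return out

    # -- dendropy bridge ---------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Phylogeny":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=int)
        blen = np.zeros(len(nodes))
        labels: list[str | None] = [None] * len(nodes)
        missing = 0
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    missing += 1
                    blen[i] = 0.0
                else:
                    blen[i] = float(nd.edge.length)
            if nd.is_leaf():
                labels[i] = nd.taxon.label if nd.taxon is not None else None
        if missing:
            warnings.warn(f"{missing} branch length(s) missing; set to 0", stacklevel=3)
        return cls(parent, blen, labels)

    def to_dendropy(self, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=tns)
        dnodes = {self.root: dtree.seed_node}
        for v in self.preorder():
            if v == self.root:
                continue
            nd = dendropy.Node()
            nd.edge.length = float(self.branch_lengths[v])
            dnodes[self.parent[v]].add_child(nd)
            dnodes[v] = nd
        for i in self.tip_indices():
            dnodes[i].taxon = tns.require_taxon(label=self.labels[i])
        return dtree


# -- Newick / Nexus I/O ----------------------------------------------------


def parse_newick(text: str, underscores_as_spaces: bool = False) -> Phylogeny:
    """Parse a single Newick string into a :class:`Phylogeny`.

    Missing branch lengths become 0 with a warning; duplicate tip labels and
    malformed input raise :class:`TreeError`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=not underscores_as_spaces,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"Newick parse error: {exc}") from exc
    return Phylogeny.from_dendropy(dtree)


_NEWICK_SAFE = frozenset(
    "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_.-"
)


def _quote_label(label: str) -> str:
    if label and set(label) <= _NEWICK_SAFE:
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: Phylogeny, precision: int = 10) -> str:
    """Serialize to Newick with branch lengths at ``precision`` significant digits."""
    fmt = f"%.{precision}g"

    def render(v: int) -> str:
        if not tree.children[v]:
            body = _quote_label(tree.labels[v])
        else:
            body = "(" + ",".join(render(c) for c in tree.children[v]) + ")"
        if v == tree.root:
            return body
        return body + ":" + (fmt % tree.branch_lengths[v])

    return render(tree.root) + ";"


class TreeSet(list):
    """Ordered collection of :class:`Phylogeny` over a shared tip-label set."""

    def __init__(self, trees):
        super().__init__(trees)
        if not self:
            raise TreeError("TreeSet must be non-empty")
        ref = set(self[0].tip_labels)
        for k, t in enumerate(self):
            labs = set(t.tip_labels)
            if labs != ref:
                extra = sorted(labs - ref)
                missing = sorted(ref - labs)
                raise TreeError(
                    f"tree {k} label set mismatch: extra={extra}, missing={missing}"
                )

    @property
    def tip_label_set(self) -> frozenset[str]:
        return frozenset(self[0].tip_labels)


def read_trees(path_or_text, schema: str = "newick") -> TreeSet:
    """Read one or more trees from a Newick or Nexus file (or literal string).

    Nexus TREES blocks with translate tables are handled by dendropy.
    """
    kwargs = {"schema": schema}
    if schema == "newick":
        kwargs["preserve_underscores"] = True
    if isinstance(path_or_text, str) and ("(" in path_or_text or "#NEXUS" in path_or_text.upper()):
        src = {"data": path_or_text}
    else:
        src = {"path": str(path_or_text)}
    try:
        tlist = dendropy.TreeList.get(**src, **kwargs)
    except Exception as exc:
        raise TreeError(f"could not read trees ({schema}): {exc}") from exc
    return TreeSet([Phylogeny.from_dendropy(t) for t in tlist])


# -- majority-rule consensus ----------------------------------------------


def consensus_tree(trees: TreeSet, threshold: float = 0.5) -> Phylogeny:
    """Majority-rule consensus over rooted clades, with averaged branch lengths.

    A clade is kept iff its frequency exceeds ``threshold`` (strictly, at the
    default 0.5; at-or-above for larger thresholds).  Each kept edge's length
    is the arithmetic mean of the subtending edge length over the trees that
    contain the clade.  The output may be non-binary.
    """
    if not isinstance(trees, TreeSet):
        trees = TreeSet(trees)
    if not 0.5 <= threshold <= 1.0:
        raise TreeError("threshold must lie in [0.5, 1]")
    n = len(trees)
    full = trees.tip_label_set
    counts: dict[frozenset, int] = {}
    length_sums: dict[frozenset, float] = {}
    for t in trees:
        sets = t.clade_tipsets()
        for v, s in sets.items():
            if v == t.root:
                continue
            counts[s] = counts.get(s, 0) + 1
            length_sums[s] = length_sums.get(s, 0.0) + float(t.branch_lengths[v])

    strict = abs(threshold - 0.5) < 1e-12

    def kept(freq: float) -> bool:
        return freq > threshold + 1e-12 if strict else freq >= threshold - 1e-12

    clades = [s for s, c in counts.items() if len(s) > 1 and kept(c / n)]
    singletons = [frozenset([lab]) for lab in sorted(full)]
    # Nesting construction: all kept clades are pairwise compatible because
    # each occurs in a strict majority of the trees.
    ordered = [full] + sorted(clades, key=len, reverse=True)
    parent_of: dict[frozenset, frozenset] = {}
    for s in ordered[1:] + singletons:
        best = None
        for cand in ordered:
            if s < cand and (best is None or len(cand) < len(best)):
                best = cand
        parent_of[s] = best

    index = {full: 0}
    parent = [-1]
    blen = [0.0]
    labels: list[str | None] = [None]
    for s in ordered[1:] + singletons:
        index[s] = len(parent)
        parent.append(index[parent_of[s]])
        blen.append(length_sums[s] / counts[s])
        labels.append(next(iter(s)) if len(s) == 1 else None)
    return Phylogeny(parent, blen, labels)


# -- penalized-likelihood dating ------------------------------------------


@dataclass
class DatingConfig:
    """Settings for penalized-likelihood ultrametricization.

    ``smoothing`` is the rate-smoothness penalty weight (dimensionless, > 0);
    ``root_age`` fixes the output depth so downstream times are relative;
    ``tolerance`` bounds the permitted tip-depth spread of the result.
    """

    smoothing: float = 1.0
    root_age: float = 1.0
    tolerance: float = 1e-6
    max_iter: int = 2000

    def __post_init__(self):
        if self.smoothing <= 0:
            raise ValueError("smoothing must be > 0")
        if self.root_age <= 0:
            raise ValueError("root_age must be > 0")


def pl_objective(tree: Phylogeny, ages: np.ndarray, rates: np.ndarray, smoothing: float) -> float:
    """Penalized objective: squared rate-likelihood misfit plus rate roughness.

    ``ages[v]`` is time before present (tips 0), ``rates[v]`` the rate on the
    edge above ``v``.  The data term is sum_e (b_e - r_e t_e)^2; the penalty
    is ``smoothing`` times the summed squared rate difference over
    parent-child edge pairs.
    """
    obj = 0.0
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        t_e = ages[tree.parent[v]] - ages[v]
        obj += (tree.branch_lengths[v] - rates[v] * t_e) ** 2
        p = tree.parent[v]
        if p != tree.root:
            obj += smoothing * (rates[p] - rates[v]) ** 2
    return obj


def date_tree_pl(tree: Phylogeny, cfg: DatingConfig | None = None) -> Phylogeny:
    """Ultrametricize a tree by joint penalized-likelihood estimation of
    node ages and branch rates.

    Node ages (root fixed at ``cfg.root_age``, tips at 0) and per-edge rates
    are optimized to minimize :func:`pl_objective` subject to parent ages
    exceeding child ages; ages are parameterized as fractions of the parent
    age so the constraint holds by construction.
    """
    cfg = cfg or DatingConfig()
    if np.any(tree.branch_lengths[np.arange(tree.n_nodes) != tree.root] < 0):
        raise TreeError("input branch lengths must be >= 0")

    pre = tree.preorder()
    internal = [v for v in pre if tree.children[v] and v != tree.root]
    edges = [v for v in range(tree.n_nodes) if v != tree.root]
    tipset = set(tree.tip_indices())

    # init ages from max root-to-tip path structure
    depth = tree.node_depths()
    height = np.zeros(tree.n_nodes)  # max distance to a descendant tip
    for v in tree.postorder():
        if tree.children[v]:
            height[v] = max(height[c] + tree.branch_lengths[c] for c in tree.children[v])
    total = depth + height
    ages0 = np.zeros(tree.n_nodes)
    for v in pre:
        ages0[v] = cfg.root_age * (height[v] / total[v]) if total[v] > 0 else 0.0
    ages0[tree.root] = cfg.root_age

    fracs0 = []
    for v in internal:
        f = ages0[v] / ages0[tree.parent[v]] if ages0[tree.parent[v]] > 0 else 0.5
        fracs0.append(np.clip(f, 0.02, 0.98))
    scale = tree.branch_lengths[edges].mean() / max(
        np.mean([ages0[tree.parent[v]] - ages0[v] for v in edges]), 1e-9
    )
    rates0 = np.full(len(edges), max(scale, 1e-6))

    n_int = len(internal)

    def unpack(x):
        ages = np.zeros(tree.n_nodes)
        ages[tree.root] = cfg.root_age
        fr = expit(x[:n_int])
        for k, v in enumerate(internal):
            ages[v] = ages[tree.parent[v]] * fr[k]
        rates = np.exp(x[n_int:])
        return ages, rates

    edge_pos = {v: k for k, v in enumerate(edges)}
    pair_i = np.array([edge_pos[tree.parent[v]] for v in edges if tree.parent[v] != tree.root], dtype=int)
    pair_j = np.array([edge_pos[v] for v in edges if tree.parent[v] != tree.root], dtype=int)
    b_e = tree.branch_lengths[edges]

    def fun(x):
        ages, rates = unpack(x)
        t_e = ages[tree.parent[edges]] - ages[edges]
        obj = float(np.sum((b_e - rates * t_e) ** 2))
        if len(pair_i):
            obj += cfg.smoothing * float(np.sum((rates[pair_i] - rates[pair_j]) ** 2))
        return obj

    x0 = np.concatenate([logit(np.asarray(fracs0)) if n_int else np.empty(0), np.log(rates0)])
    res = minimize(fun, x0, method="L-BFGS-B", options={"maxiter": cfg.max_iter, "maxfun": 10 * cfg.max_iter})
    if not (res.success or res.status == 1):  # status 1 = maxiter, still usable if feasible
        raise TreeError(f"penalized-likelihood dating did not converge: {res.message}")
    ages, _ = unpack(res.x)

    out = tree.copy()
    for v in edges:
        out.branch_lengths[v] = ages[tree.parent[v]] - ages[v]
    spread = np.ptp([out.node_depths()[i] for i in tipset])
    if spread > cfg.tolerance * cfg.root_age:
        raise TreeError(f"dating result not ultrametric within tolerance (spread={spread:g})")
    return out
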