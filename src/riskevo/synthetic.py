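"""Seeded generators for trees and trait data with the structure the
analysis assumes: Yule time-trees, discrete ER-Markov tip states (under any
of the rate-through-time models), Brownian tip values, and a fixture
emulating the endemic-bird dataset (48 species, category composition
EN 1 / VU 14 / NT 9 / LC 24).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mk_models import ModelSpec, transform_branches
from .risk_coding import CodedStates
from .trees import Phylogeny, write_newick

FIXTURE_CATEGORY_COUNTS = {"EN": 1, "VU": 14, "NT": 9, "LC": 24}


class SimulationError(ValueError):
    """Raised for invalid simulation settings."""


@dataclass
class SimConfig:
    n_tips: int
    seed: int
    birth_rate: float = 1.0
    death_rate: float = 0.0
    model: ModelSpec | None = None
    bm_rate: float = 1.0

    def __post_init__(self):
        if self.n_tips < 2:
            raise SimulationError("n_tips must be >= 2")
        if self.birth_rate <= 0:
            raise SimulationError("birth_rate must be > 0")
        if self.death_rate < 0:
            raise SimulationError("death_rate must be >= 0")
        if self.bm_rate <= 0:
            raise SimulationError("bm_rate must be > 0")


def simulate_yule(cfg: SimConfig | None = None, *, n_tips: int | None = None,
                  seed: int | None = None, birth_rate: float = 1.0) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree, rescaled to depth 1.

    Lineages split at exponential waiting times with total rate
    birth_rate * (number of lineages); once ``n_tips`` lineages exist, all
    are extended to the final time so the tree is exactly ultrametric.
    """
    if cfg is None:
        cfg = SimConfig(n_tips=n_tips, seed=seed, birth_rate=birth_rate)
    rng = np.random.default_rng(cfg.seed)

    parent = [-1]
    blen = [0.0]
    birth_time = [0.0]
    active = [0]
    t = 0.0
    while len(active) < cfg.n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (cfg.birth_rate * k))
        pick = active[rng.integers(k)]
        for _ in range(2):
            parent.append(pick)
            blen.append(0.0)
            birth_time.append(t)
            active.append(len(parent) - 1)
        active.remove(pick)
        if pick != 0:  # root carries no branch above it
            blen[pick] = t - birth_time[pick]
    t_end = t + rng.exponential(1.0 / (cfg.birth_rate * cfg.n_tips))
    for v in active:
        blen[v] = t_end - birth_time[v]

    labels: list[str | None] = [None] * len(parent)
    tip_ids = sorted(active)
    for i, v in enumerate(tip_ids):
        labels[v] = f"t{i + 1:03d}"
    tree = Phylogeny(parent, blen, labels)
    return tree.rescaled_to_depth(1.0)


def simulate_mk(tree: Phylogeny, spec: ModelSpec | None, seed: int, k: int = 4,
                q: float | None = None) -> CodedStates:
    """Simulate discrete states (1..k) down the tree under the ER process.

    The root state is uniform; transitions use the ER closed form on the
    branch lengths of the (transform-adjusted) tree, so any rate-through-
    time model supported by :func:`transform_branches` can generate data.
    ``q`` alone may be given as shorthand for a constant-rate model.
    """
    if spec is None:
        if q is None:
            raise SimulationError("provide a ModelSpec or a rate q")
        spec = ModelSpec(kind="null", q=q)
    rng = np.random.default_rng(seed)
    work = transform_branches(tree, spec) if spec.kind != "null" else tree
    qrate = spec.q
    states = np.zeros(tree.n_nodes, dtype=int)
    states[tree.root] = rng.integers(k)
    for v in work.preorder():
        if v == work.root:
            continue
        e = np.exp(-k * qrate * work.branch_lengths[v])
        if rng.random() < e:
            states[v] = states[work.parent[v]]
        else:
            states[v] = rng.integers(k)
    out = {}
    for i in tree.tip_indices():
        out[tree.labels[i]] = int(states[i]) + 1
    return CodedStates(states=out)


def simulate_bm_many(tree: Phylogeny, rate: float, n_rep: int, rng,
                     tip_order: list[int] | None = None) -> np.ndarray:
    """``n_rep`` Brownian tip-value vectors (rows) from root value 0.

    Per-branch increments are Normal(0, rate * length), accumulated root to
    tip; vectorized over replicates.
    """
    if rate <= 0:
        raise SimulationError("BM rate must be > 0")
    vals = np.zeros((tree.n_nodes, n_rep))
    sd = np.sqrt(rate * np.clip(tree.branch_lengths, 0.0, None))
    for v in tree.preorder():
        if v == tree.root:
            continue
        vals[v] = vals[tree.parent[v]] + rng.normal(0.0, sd[v], size=n_rep)
    tips = tip_order if tip_order is not None else tree.tip_indices()
    return vals[tips].T.copy()


def simulate_bm(tree: Phylogeny, bm_rate: float, seed: int) -> dict[str, float]:
    """Single Brownian replicate as a tip-label -> value map."""
    rng = np.random.default_rng(seed)
    tips = tree.tip_indices()
    row = simulate_bm_many(tree, bm_rate, 1, rng, tip_order=tips)[0]
    return {tree.labels[v]: float(x) for v, x in zip(tips, row)}


def make_fixture_dataset(seed: int, out_dir=None):
    """Synthetic stand-in for the endemic-bird dataset.

    Returns (risk-table DataFrame, dated tree) — 48 pseudo-species
    ("Genus_sp01" ...) with the real category composition (EN 1, VU 14,
    NT 9, LC 24) on a seeded 48-tip Yule tree over the same names.  If
    ``out_dir`` is given, writes ``risk_table.csv`` and ``tree.nwk`` there
    and returns their paths as well.
    """
    rng = np.random.default_rng(seed)
    n = sum(FIXTURE_CATEGORY_COUNTS.values())
    cats = [c for c, k in FIXTURE_CATEGORY_COUNTS.items() for _ in range(k)]
    rng.shuffle(cats)
    names = [f"Genus_sp{i + 1:02d}" for i in range(n)]
    table = pd.DataFrame({
        "order": "Simuliformes",
        "family": "Syntheticidae",
        "species": names,
        "common_name": [f"Synthetic bird {i + 1}" for i in range(n)],
        "iucn": cats,
    })
    tree = simulate_yule(SimConfig(n_tips=n, seed=int(rng.integers(2**31 - 1))))
    for i, v in enumerate(tree.tip_indices()):
        tree.labels[v] = names[i]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table_path = out_dir / "risk_table.csv"
        tree_path = out_dir / "tree.nwk"
        table.to_csv(table_path, index=False)
        tree_path.write_text(write_newick(tree) + "\n")
        return table, tree, table_path, tree_path
    return table, tree
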