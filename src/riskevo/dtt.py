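"""Disparity-through-time (DTT) analysis of coded extinction-risk states.

At each internal-node time of an ultrametric tree, the mean relative
disparity of the lineages alive just before that splitting event is
computed: for each lineage (branch crossing the time point) the disparity
of the tip values descending from it, averaged over lineages, standardized
by the whole-clade disparity.  The curve starts at 1 at the root and drops
toward 0 when variation is partitioned *between* subclades (trait
conservatism); values above a randomization null toward the present
indicate that risk categories stay similar within subclades.

The null is either Brownian-motion simulation with a rate fitted by ML to
the observed states (the convention of the DTT literature), or a tip
shuffle of the observed states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import Phylogeny
from .synthetic import simulate_bm_many


class DTTError(ValueError):
    """Raised for invalid disparity-through-time input."""


@dataclass
class DTTConfig:
    metric: str = "avg_sq"  # or "avg_abs"
    n_sim: int = 1000
    null_method: str = "bm_sim"  # or "tip_shuffle"
    seed: int = 0
    quantiles: tuple[float, float] = (0.025, 0.975)

    def __post_init__(self):
        if self.metric not in ("avg_sq", "avg_abs"):
            raise DTTError(f"unknown metric {self.metric!r}")
        if self.null_method not in ("bm_sim", "tip_shuffle"):
            raise DTTError(f"unknown null method {self.null_method!r}")
        if self.n_sim < 1:
            raise DTTError("n_sim must be >= 1")


@dataclass
class DTTCurve:
    """Observed DTT curve with its randomization null."""

    times: np.ndarray
    observed: np.ndarray
    null_curves: np.ndarray | None = None
    null_median: np.ndarray | None = None
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None
    n_sim: int = 0
    config: DTTConfig | None = None


def disparity(values, metric: str = "avg_sq") -> float:
    """Mean pairwise distance among values.

    ``avg_sq`` averages squared differences over unordered pairs,
    ``avg_abs`` absolute differences.  A single value has disparity 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise DTTError("disparity of an empty set is undefined")
    n = x.size
    if n == 1:
        return 0.0
    if metric == "avg_sq":
        # sum over pairs of (xi-xj)^2 equals n * sum(x^2) - (sum x)^2
        s, s2 = x.sum(), (x * x).sum()
        return float((n * s2 - s * s) / (n * (n - 1) / 2.0))
    if metric == "avg_abs":
        xs = np.sort(x)
        coef = 2 * np.arange(n) - (n - 1)
        return float((coef * xs).sum() / (n * (n - 1) / 2))
    raise DTTError(f"unknown metric {metric!r}")


class _CurveEvaluator:
    """Precomputed lineage structure: which tip sets are averaged at each
    internal-node time.  Built once per tree, then applied to many tip-value
    vectors (observed and null replicates)."""

    def __init__(self, tree: Phylogeny, metric: str):
        if not tree.is_ultrametric(1e-6):
            raise DTTError("DTT requires an ultrametric tree")
        self.metric = metric
        rel = tree.relative_times()
        tips = tree.tip_indices()
        self.tip_order = tips
        tip_pos = {v: i for i, v in enumerate(tips)}

        clade: dict[int, np.ndarray] = {}
        for v in tree.postorder():
            if not tree.children[v]:
                clade[v] = np.array([tip_pos[v]], dtype=int)
            else:
                clade[v] = np.concatenate([clade[c] for c in tree.children[v]])

        internal = tree.internal_indices()
        times = sorted(float(rel[v]) for v in internal)
        eps = 1e-9
        self.times = np.array(times)
        self.lineages: list[list[np.ndarray]] = []
        all_tips = np.arange(len(tips))
        for i, t in enumerate(times):
            if i == 0:
                self.lineages.append([all_tips])  # the root stem: whole clade
                continue
            sets = [
                clade[v]
                for v in range(tree.n_nodes)
                if v != tree.root and rel[tree.parent[v]] < t - eps and rel[v] >= t - eps
            ]
            self.lineages.append(sets)

    def curve(self, tip_values: np.ndarray) -> np.ndarray:
        total = disparity(tip_values, self.metric)
        if total <= 0:
            raise DTTError("no variation in states: whole-tree disparity is 0")
        out = np.empty(len(self.times))
        out[0] = 1.0
        for i in range(1, len(self.times)):
            sets = self.lineages[i]
            vals = [disparity(tip_values[s], self.metric) if len(s) > 1 else 0.0 for s in sets]
            out[i] = float(np.mean(vals)) / total
        return out


def _tip_value_vector(tree: Phylogeny, states, evaluator: _CurveEvaluator) -> np.ndarray:
    smap = states.states if hasattr(states, "states") else dict(states)
    vals = []
    for v in evaluator.tip_order:
        lab = tree.labels[v]
        if lab not in smap:
            raise DTTError(f"tip {lab!r} has no state")
        vals.append(float(smap[lab]))
    return np.array(vals)


def relative_disparity_curve(tree: Phylogeny, states, cfg: DTTConfig | None = None):
    """Observed DTT curve: times (internal-node relative times, root first)
    and relative disparity values."""
    cfg = cfg or DTTConfig()
    ev = _CurveEvaluator(tree, cfg.metric)
    obs = ev.curve(_tip_value_vector(tree, states, ev))
    return ev.times.copy(), obs


def _fit_bm_rate(tree: Phylogeny, x: np.ndarray, tip_order: list[int]) -> float:
    """ML Brownian rate for tip values on the tree (shared-depth covariance)."""
    depth = tree.node_depths()
    scale = tree.max_depth()
    n = len(tip_order)
    tip_pos = {v: i for i, v in enumerate(tip_order)}
    C = np.zeros((n, n))
    clade: dict[int, list[int]] = {}
    for v in tree.postorder():
        if not tree.children[v]:
            clade[v] = [tip_pos[v]]
        else:
            clade[v] = [i for c in tree.children[v] for i in clade[c]]
    for v in tree.preorder():  # children later: deeper MRCA depths overwrite
        idx = np.array(clade[v], dtype=int)
        C[np.ix_(idx, idx)] = depth[v] / scale
    np.fill_diagonal(C, [depth[v] / scale for v in tip_order])
    Cinv_x = np.linalg.solve(C, x)
    Cinv_1 = np.linalg.solve(C, np.ones(n))
    mu = float(Cinv_1 @ x) / float(Cinv_1.sum())
    r = x - mu
    sigma2 = float(r @ np.linalg.solve(C, r)) / n
    return max(sigma2, 1e-12)


def dtt_null(tree: Phylogeny, states, cfg: DTTConfig | None = None) -> DTTCurve:
    """Observed curve plus a randomization null and its pointwise envelope.

    ``bm_sim`` fits a Brownian rate to the observed states and simulates
    ``n_sim`` continuous tip datasets; ``tip_shuffle`` permutes the observed
    states across tips.  Fully seeded and reproducible.
    """
    cfg = cfg or DTTConfig()
    rng = np.random.default_rng(cfg.seed)
    ev = _CurveEvaluator(tree, cfg.metric)
    x = _tip_value_vector(tree, states, ev)
    obs = ev.curve(x)

    null = np.empty((cfg.n_sim, len(ev.times)))
    if cfg.null_method == "bm_sim":
        rate = _fit_bm_rate(tree, x, ev.tip_order)
        sims = simulate_bm_many(tree, rate, cfg.n_sim, rng, tip_order=ev.tip_order)
        for r in range(cfg.n_sim):
            null[r] = ev.curve(sims[r])
    else:
        for r in range(cfg.n_sim):
            null[r] = ev.curve(rng.permutation(x))

    lo_q, hi_q = cfg.quantiles
    return DTTCurve(
        times=ev.times.copy(),
        observed=obs,
        null_curves=null,
        null_median=np.median(null, axis=0),
        lo=np.quantile(null, lo_q, axis=0),
        hi=np.quantile(null, hi_q, axis=0),
        n_sim=cfg.n_sim,
        config=cfg,
    )


def conservatism_report(curve: DTTCurve) -> pd.DataFrame:
    """Per-time classification of the observed curve against the null
    envelope, plus a mean observed-minus-null summary (MDI-style; positive
    under conservatism).

    Calls: ``conservatism`` where observed exceeds the upper quantile,
    ``overdispersion`` below the lower quantile, ``ns`` otherwise.
    """
    if curve.lo is None or curve.hi is None:
        raise DTTError("curve has no null envelope; run dtt_null first")
    calls = np.where(
        curve.observed > curve.hi,
        "conservatism",
        np.where(curve.observed < curve.lo, "overdispersion", "ns"),
    )
    df = pd.DataFrame({
        "time": curve.times,
        "observed": curve.observed,
        "null_median": curve.null_median,
        "lo": curve.lo,
        "hi": curve.hi,
        "call": calls,
    })
    df.attrs["mdi"] = float(np.mean(curve.observed - curve.null_median))
    return df


def plot_dtt(curve: DTTCurve, path=None):
    """Basic DTT figure: observed curve, null median, and envelope."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(curve.times, curve.lo, curve.hi, alpha=0.25, label="null envelope")
    ax.plot(curve.times, curve.null_median, "--", label="null median")
    ax.plot(curve.times, curve.observed, "-", lw=2, label="observed")
    ax.set_xlabel("relative time (0 = root, 1 = present)")
    ax.set_ylabel("relative disparity")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
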