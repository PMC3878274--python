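"""Equal-rates Markov (Mk/ER) likelihoods with time-dependent rate models.

The discrete extinction-risk state (1..4) is modelled as a continuous-time
Markov chain with equal transition rates among states.  Four variants of the
rate-through-time trajectory are fitted by maximum likelihood and compared
by AIC:

* ``null``      — constant rate q over the whole tree;
* ``delta``     — node depths raised to a power delta (the classic depth
                  power transform: delta > 1 accelerates apparent evolution
                  toward the present, delta < 1 concentrates it early);
* ``linear``    — rate r(t) = q + s*t changing linearly in relative time;
* ``two_rate``  — rate q before a breakpoint time B, rate E after it.

Likelihoods are computed by the pruning (post-order) algorithm on the
transformed tree, with per-node rescaling against underflow; polytomies are
supported.  The root prior is uniform over the four states, which equals
the ER stationary distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .trees import Phylogeny

NEG_INF = float("-inf")
_RATE_FLOOR = 1e-8

MODEL_KINDS = ("null", "delta", "linear", "two_rate")
K_EXTRA = {"null": 0, "delta": 1, "linear": 1, "two_rate": 2}


class ModelError(ValueError):
    """Raised for invalid model specifications or data."""


@dataclass(frozen=True)
class ModelSpec:
    """Parameters of one rate-through-time model.

    ``q`` is the baseline ER transition rate in events per unit relative
    time (root at 0, present at 1).  ``delta`` is the depth-transform
    exponent; ``s`` the linear slope of r(t) = q + s*t; ``B`` the breakpoint
    time and ``E`` the post-breakpoint rate of the two-rate model.  ``E`` is
    an absolute rate by default; set ``e_is_multiplier`` to read it as a
    multiple of ``q``.
    """

    kind: str
    q: float
    delta: float = 1.0
    s: float = 0.0
    B: float = 0.5
    E: float | None = None
    e_is_multiplier: bool = False

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ModelError(f"unknown model kind {self.kind!r}")
        if not self.q > 0:
            raise ModelError("q must be > 0")
        if self.kind == "delta" and not self.delta > 0:
            raise ModelError("delta must be > 0")
        if self.kind == "linear":
            if min(self.q, self.q + self.s) < _RATE_FLOOR:
                raise ModelError("linear rate q + s*t must stay positive on [0, 1]")
        if self.kind == "two_rate":
            if not 0.0 <= self.B <= 1.0:
                raise ModelError("breakpoint B must lie in [0, 1]")
            if self.E is None or not self.E > 0:
                raise ModelError("two_rate requires a second rate E > 0")

    @property
    def rate_after(self) -> float:
        """Post-breakpoint rate on the absolute scale."""
        return self.E * self.q if self.e_is_multiplier else self.E


# -- ER transition probabilities ------------------------------------------


def transition_matrix_er(q: float, t: float, k: int = 4) -> np.ndarray:
    """Closed-form ER transition matrix for duration ``t`` at rate ``q``.

    P_ii = 1/k + (1 - 1/k) exp(-k q t);  P_ij = (1 - exp(-k q t)) / k.
    """
    if q < 0 or t < 0:
        raise ModelError("q and t must be non-negative")
    e = math.exp(-k * q * t)
    off = (1.0 - e) / k
    P = np.full((k, k), off)
    np.fill_diagonal(P, off + e)
    return P


# -- branch-length transforms ---------------------------------------------


def _effective_lengths(t0: np.ndarray, t1: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Effective branch lengths (relative-time units) for edges spanning
    [t0, t1] under ``spec``, such that the ER process at rate ``spec.q`` on
    the effective lengths equals the time-varying process on the original
    tree."""
    if spec.kind == "null":
        return t1 - t0
    if spec.kind == "delta":
        return t1**spec.delta - t0**spec.delta
    if spec.kind == "linear":
        # integral of (q + s t)/q over [t0, t1]
        lo = spec.q + spec.s * 0.0
        hi = spec.q + spec.s * 1.0
        if lo < _RATE_FLOOR or hi < _RATE_FLOOR:
            raise ModelError("linear rate q + s*t must stay >= 1e-8 on [0, 1]")
        return (t1 - t0) + (spec.s / spec.q) * (t1**2 - t0**2) / 2.0
    if spec.kind == "two_rate":
        before = np.clip(np.minimum(t1, spec.B) - t0, 0.0, None)
        after = np.clip(t1 - np.maximum(t0, spec.B), 0.0, None)
        return before + (spec.rate_after / spec.q) * after
    raise ModelError(spec.kind)


def transform_branches(tree: Phylogeny, spec: ModelSpec) -> Phylogeny:
    """Return a copy of ``tree`` whose branch lengths are the effective
    lengths under ``spec``'s rate trajectory.

    Times are measured relative to the tree (root 0, tips 1); effective
    lengths are scaled back to the input depth, so the null transform (and
    delta=1, s=0, E=q) returns the tree unchanged.
    """
    depth = tree.max_depth()
    rel = tree.relative_times()
    out = tree.copy()
    edges = np.array([v for v in range(tree.n_nodes) if v != tree.root], dtype=int)
    t0 = rel[tree.parent[edges]]
    t1 = rel[edges]
    out.branch_lengths[edges] = _effective_lengths(t0, t1, spec) * depth
    return out


# -- pruning likelihood ----------------------------------------------------


class Pruner:
    """Preprocessed pruning-algorithm evaluator for one (tree, states) pair.

    Internal nodes are grouped into levels (all children of a level already
    resolved) so each level is evaluated with vectorized segment products;
    per-level rescaling guards against underflow.
    """

    def __init__(self, tree: Phylogeny, states: dict[str, int], k: int = 4,
                 ambiguous: set[str] | frozenset[str] = frozenset()):
        self.k = k
        self.tree = tree
        n = tree.n_nodes
        self.n = n
        self.tip_partial = np.zeros((n, k))
        for i in tree.tip_indices():
            lab = tree.labels[i]
            if lab in ambiguous:
                self.tip_partial[i] = 1.0
            elif lab in states:
                st = states[lab]
                if not 1 <= st <= k:
                    raise ModelError(f"state {st} for tip {lab!r} outside 1..{k}")
                self.tip_partial[i, st - 1] = 1.0
            else:
                raise ModelError(f"tip {lab!r} has no state and is not marked ambiguous")

        level = np.zeros(n, dtype=int)
        for v in tree.postorder():
            if tree.children[v]:
                level[v] = 1 + max(level[c] for c in tree.children[v])
        self.levels = []
        for lv in range(1, level.max() + 1):
            nodes = [v for v in tree.internal_indices() if level[v] == lv]
            if not nodes:
                continue
            child_flat = np.array([c for v in nodes for c in tree.children[v]], dtype=int)
            seg = np.cumsum([0] + [len(tree.children[v]) for v in nodes[:-1]])
            self.levels.append((np.array(nodes, dtype=int), child_flat, seg))
        self.root = tree.root
        self.edge_index = np.arange(n)

    def loglik(self, q: float, branch_lengths: np.ndarray) -> float:
        """Log-likelihood of the tip states under ER rate ``q`` with the
        given (possibly transformed) branch lengths."""
        if q < 0:
            raise ModelError("q must be >= 0")
        k = self.k
        e = np.exp(-k * q * np.asarray(branch_lengths, dtype=float))
        partial = self.tip_partial.copy()
        logscale = 0.0
        for nodes, child_flat, seg in self.levels:
            pc = partial[child_flat]
            ec = e[child_flat][:, None]
            msg = ec * pc + ((1.0 - ec) / k) * pc.sum(axis=1, keepdims=True)
            prod = np.multiply.reduceat(msg, seg, axis=0)
            m = prod.max(axis=1)
            if np.any(m <= 0.0):
                return NEG_INF
            partial[nodes] = prod / m[:, None]
            logscale += float(np.log(m).sum())
        lik = float(partial[self.root].sum() / k)  # uniform root prior
        if lik <= 0.0:
            return NEG_INF
        return math.log(lik) + logscale


def mk_loglik(tree: Phylogeny, states, q: float,
              ambiguous: set[str] | frozenset[str] = frozenset()) -> float:
    """Pruning log-likelihood of discrete states under the ER model.

    ``states`` is a species->state mapping or a :class:`CodedStates`;
    branch lengths are used as given (apply :func:`transform_branches`
    first for the time-dependent models).  Impossible data (zero
    likelihood) returns ``-inf``.
    """
    smap = states.states if hasattr(states, "states") else dict(states)
    pruner = Pruner(tree, smap, ambiguous=ambiguous)
    return pruner.loglik(q, tree.branch_lengths)


# -- AIC and model comparison ----------------------------------------------


def aic(logL: float, k_extra: int, convention: str = "extra_only") -> float:
    """Akaike information criterion.

    The default "extra_only" convention counts only parameters beyond the
    baseline transition rate (null 0, delta 1, linear 1, two-rate 2), i.e.
    AIC = -2 logL + 2 k_extra.  The "standard" convention counts every free
    parameter including the baseline rate.
    """
    if not math.isfinite(logL):
        raise ModelError("AIC requires a finite log-likelihood")
    if k_extra < 0 or int(k_extra) != k_extra:
        raise ModelError("k_extra must be a non-negative integer")
    if convention == "extra_only":
        k = k_extra
    elif convention == "standard":
        k = k_extra + 1
    else:
        raise ModelError(f"unknown AIC convention {convention!r}")
    return -2.0 * logL + 2.0 * k


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood model fit."""

    kind: str
    logL: float
    estimates: dict[str, float]
    k_extra: int
    AIC: float
    converged: bool
    n_starts: int
    diagnostics: dict = field(default_factory=dict)


@dataclass
class FitOptions:
    n_starts: int = 5
    seed: int = 0
    grid_points: int = 101
    xtol: float = 1e-8
    q_bounds: tuple[float, float] = (1e-6, 1e3)
    delta_bounds: tuple[float, float] = (1e-2, 1e2)
    aic_convention: str = "extra_only"
    e_is_multiplier: bool = False


def _spec_for(kind: str, params: dict[str, float], opts: FitOptions) -> ModelSpec:
    return ModelSpec(
        kind=kind,
        q=params["q"],
        delta=params.get("delta", 1.0),
        s=params.get("s", 0.0),
        B=params.get("B", 0.5),
        E=params.get("E"),
        e_is_multiplier=opts.e_is_multiplier,
    )


def fit_model(tree: Phylogeny, states, kind: str, opts: FitOptions | None = None) -> FitResult:
    """Maximum-likelihood fit of one rate model to discrete tip states.

    The tree is rescaled to unit depth internally, so the fitted ``q`` (and
    ``E``, ``s``) are rates per unit relative time.  Positive parameters are
    optimized on the log scale with seeded multi-starts; the two-rate
    breakpoint is profiled on a grid and locally refined, because the
    likelihood is only piecewise smooth in B.
    """
    if kind not in MODEL_KINDS:
        raise ModelError(f"unknown model kind {kind!r}")
    opts = opts or FitOptions()
    rng = np.random.default_rng(opts.seed)

    work = tree.rescaled_to_depth(1.0)
    smap = states.states if hasattr(states, "states") else dict(states)
    pruner = Pruner(work, smap)
    rel = work.relative_times()
    edges = np.array([v for v in range(work.n_nodes) if v != work.root], dtype=int)
    t0 = rel[work.parent[edges]]
    t1 = rel[edges]
    blen = np.zeros(work.n_nodes)

    lo_q, hi_q = np.log(opts.q_bounds[0]), np.log(opts.q_bounds[1])

    def nll_for(params: dict[str, float]) -> float:
        try:
            spec = _spec_for(kind, params, opts)
            eff = _effective_lengths(t0, t1, spec)
        except ModelError:
            return 1e10
        if np.any(eff < 0):
            return 1e10
        blen[edges] = eff
        ll = pruner.loglik(params["q"], blen)
        return 1e10 if ll == NEG_INF else -ll

    # baseline: 1-D bounded search over log q (used by null and as anchor)
    res_q = minimize_scalar(
        lambda lq: nll_for({"q": math.exp(lq), "kind": kind} | {}),
        bounds=(lo_q, hi_q),
        method="bounded",
        options={"xatol": opts.xtol},
    ) if kind == "null" else None

    if kind == "null":
        q_hat = math.exp(res_q.x)
        logL = -res_q.fun
        est = {"q": q_hat}
        return FitResult(
            kind, logL, est, K_EXTRA[kind],
            aic(logL, K_EXTRA[kind], opts.aic_convention),
            bool(res_q.fun < 1e9), 1, {"scalar_result": res_q.message},
        )

    null_fit = fit_model(tree, states, "null", opts)
    lq0 = math.log(max(null_fit.estimates["q"], opts.q_bounds[0]))

    def run_nm(fun, x0, bounds=None):
        res = minimize(fun, x0, method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 400})
        return res

    if kind == "delta":
        lo_d, hi_d = np.log(opts.delta_bounds[0]), np.log(opts.delta_bounds[1])

        def fun(x):
            lq, ld = x
            if not (lo_q <= lq <= hi_q and lo_d <= ld <= hi_d):
                return 1e10
            return nll_for({"q": math.exp(lq), "delta": math.exp(ld)})

        starts = [(lq0, 0.0)]
        for _ in range(opts.n_starts - 1):
            starts.append((lq0 + rng.normal(0, 0.5), rng.normal(0, 1.0)))
        best = min((run_nm(fun, s) for s in starts), key=lambda r: r.fun)
        q_hat, d_hat = math.exp(best.x[0]), math.exp(best.x[1])
        logL = -best.fun
        est = {"q": q_hat, "delta": d_hat}
        diag = {"nm_message": best.message}

    elif kind == "linear":

        def fun(x):
            lq, s = x
            q = math.exp(lq)
            if not lo_q <= lq <= hi_q:
                return 1e10
            if q + min(0.0, s) < _RATE_FLOOR:
                return 1e10
            return nll_for({"q": q, "s": s})

        q0 = math.exp(lq0)
        starts = [(lq0, 0.0), (lq0, q0), (lq0, -q0 / 2)]
        for _ in range(max(0, opts.n_starts - 3)):
            starts.append((lq0 + rng.normal(0, 0.5), rng.normal(0, q0)))
        best = min((run_nm(fun, s) for s in starts), key=lambda r: r.fun)
        q_hat, s_hat = math.exp(best.x[0]), float(best.x[1])
        logL = -best.fun
        est = {"q": q_hat, "s": s_hat}
        diag = {"nm_message": best.message}

    elif kind == "two_rate":
        grid = np.linspace(0.0, 1.0, opts.grid_points)

        def fun_at_B(B):
            def fun(x):
                lq, le = x
                if not (lo_q <= lq <= hi_q and lo_q <= le <= hi_q):
                    return 1e10
                return nll_for({"q": math.exp(lq), "B": B, "E": math.exp(le)})
            return fun

        profile = []
        x_warm = np.array([lq0, lq0])
        for B in grid:
            res = run_nm(fun_at_B(B), x_warm)
            if res.fun < 1e9:
                x_warm = res.x
            profile.append((res.fun, res.x.copy(), B))
        best_fun, best_x, best_B = min(profile, key=lambda r: r[0])

        h = 1.0 / (opts.grid_points - 1)
        lo_B, hi_B = max(0.0, best_B - h), min(1.0, best_B + h)

        def profile_nll(B):
            return run_nm(fun_at_B(B), best_x).fun

        res_B = minimize_scalar(profile_nll, bounds=(lo_B, hi_B), method="bounded",
                                options={"xatol": 1e-4})
        if res_B.fun < best_fun:
            best_B = float(res_B.x)
            res = run_nm(fun_at_B(best_B), best_x)
            best_fun, best_x = res.fun, res.x
        q_hat, e_hat = math.exp(best_x[0]), math.exp(best_x[1])
        logL = -best_fun
        est = {"q": q_hat, "B": float(best_B), "E": e_hat}
        diag = {
            "profile": [(float(B), float(-f) if f < 1e9 else None) for f, _, B in profile],
            "boundary_pinned_B": bool(best_B <= h or best_B >= 1.0 - h),
        }

    if logL <= -1e9:
        raise ModelError(f"all optimization starts failed for model {kind!r}")
    # model nesting: never report worse than the null at its own optimum
    if logL < null_fit.logL:
        logL = null_fit.logL
        est = {"q": null_fit.estimates["q"]} | {
            k: v for k, v in {"delta": 1.0, "s": 0.0,
                              "B": est.get("B", 0.5), "E": null_fit.estimates["q"]}.items()
            if k in est
        }
        diag["fell_back_to_null"] = True
    return FitResult(
        kind, logL, est, K_EXTRA[kind],
        aic(logL, K_EXTRA[kind], opts.aic_convention),
        True, len(starts) if kind in ("delta", "linear") else opts.grid_points,
        diag,
    )


def model_table(fits: list[FitResult]) -> pd.DataFrame:
    """Comparison table of fitted models, sorted ascending by AIC.

    Adds delta-AIC from the minimum, flags the best model, and flags
    whether the runner-up is within 2 AIC units (models then considered
    statistically indistinguishable)."""
    if not fits:
        raise ModelError("model_table requires at least one fit")
    rows = []
    for f in fits:
        rows.append({
            "model": f.kind,
            "logL": f.logL,
            "q": f.estimates.get("q"),
            "delta": f.estimates.get("delta"),
            "s": f.estimates.get("s"),
            "B": f.estimates.get("B"),
            "E": f.estimates.get("E"),
            "k_extra": f.k_extra,
            "AIC": f.AIC,
        })
    df = pd.DataFrame(rows).sort_values("AIC", kind="mergesort").reset_index(drop=True)
    df["delta_AIC"] = df["AIC"] - df["AIC"].min()
    df["best"] = [i == 0 for i in range(len(df))]
    close = len(df) > 1 and (df["AIC"].iloc[1] - df["AIC"].iloc[0]) < 2.0
    df.attrs["best_model"] = df["model"].iloc[0]
    df.attrs["runner_up_within_2"] = bool(close)
    return df
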