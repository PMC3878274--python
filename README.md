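# riskevo

Phylogenetic comparative analysis of how extinction risk evolves across a
clade. `riskevo` was built around a concrete study system — the endemic
birds of mainland China and their IUCN Red List categories — but every
stage is generic: any set of species with ordered risk categories and a
dated phylogeny can be analysed.

## What it does

IUCN categories are coded to an ordered integer state
(EN = 1, VU = 2, NT = 3, LC = 4; DD and unrecorded species are excluded
with a logged reason). Two complementary analyses are then run on an
ultrametric tree:

1. **Disparity through time (DTT).** At each internal-node time *t* of the
   tree (relative time: 0 = root, 1 = present), the mean pairwise squared
   difference of risk states within each lineage alive at *t* is averaged
   and standardized by the whole-clade disparity. The observed curve is
   compared with a randomization null — Brownian-motion simulation at the
   ML-fitted rate, or a tip shuffle — with pointwise 95% envelopes.
   Observed values above the null indicate more within-lineage disparity
   than the null process predicts; the per-time calls and an MDI-style
   mean difference summarize the pattern.

2. **Time-dependent Mk models.** The state is modelled as a 4-state
   continuous-time Markov chain with equal transition rates *q* (ER
   model), computed by Felsenstein's pruning algorithm with the closed-form
   ER transition matrix P(t) = 1/k + (1 − 1/k)·e^(−kqt) on the diagonal.
   Four rate-through-time trajectories are fitted by maximum likelihood
   and compared by AIC:

   | model | rate trajectory | free parameters |
   |---|---|---|
   | null | r(t) = q | q |
   | delta | node depths d → d^δ | q, δ |
   | linear | r(t) = q + s·t | q, s |
   | two-rate | q before breakpoint B, E after | q, B, E |

   Time-dependence is implemented exactly, by integrating the rate
   trajectory into effective branch lengths. AIC follows the
   extra-parameters-only convention (AIC = −2 logL + 2 k_extra) by
   default, with the standard all-parameters convention as an option.

Supporting machinery includes Newick/Nexus I/O (via dendropy),
majority-rule consensus over rooted clades with branch lengths averaged
over the trees containing each clade, penalized-likelihood dating
(Gaussian misfit + rate-smoothness penalty λ) to ultrametricize a
consensus tree, and fully seeded simulators (Yule trees, ER-Markov states
under any of the four models, Brownian tip values).

## Worked example

The bundled fixture generator reproduces the study's data shape: 48
species with the real category composition (EN 1, VU 14, NT 9, LC 24) on
a seeded 48-tip Yule tree.

```python
import riskevo as rv

table, tree = rv.make_fixture_dataset(seed=1)
states = rv.CodedStates(states={
    r.species: {"EN": 1, "VU": 2, "NT": 3, "LC": 4}[r.iucn]
    for r in table.itertuples()
})

fits = [rv.fit_model(tree, states, kind, rv.FitOptions(seed=1))
        for kind in ("null", "delta", "linear", "two_rate")]
print(rv.model_table(fits)[["model", "logL", "q", "B", "E", "k_extra",
                            "AIC", "delta_AIC", "best"]].round(3).to_string(index=False))

curve = rv.dtt_null(tree, states, rv.DTTConfig(n_sim=1000, seed=1))
report = rv.conservatism_report(curve)
print(f"DTT: {len(curve.times)} time points, "
      f"mean observed-null difference {report.attrs['mdi']:.3f}")
```

prints

```
   model    logL     q     B      E  k_extra     AIC  delta_AIC  best
   delta -61.045 0.275   NaN    NaN        1 124.091      0.000  True
two_rate -61.024 0.000 0.977 11.773        2 126.048      1.958 False
  linear -64.369 0.000   NaN    NaN        1 130.738      6.647 False
    null -65.446 1.291   NaN    NaN        0 130.892      6.801 False
DTT: 47 time points, mean observed-null difference 0.425
```

Read: on this synthetic dataset the depth-transform model edges out the
two-rate model, but the gap to the runner-up is below 2 AIC units, so the
two are statistically indistinguishable; the fitted breakpoint sits at
B = 0.977 — essentially the tip end of the tree, a boundary artifact
rather than a believable shift. The DTT curve starts at 1 at the root by
construction and stays above the Brownian null (positive mean
difference): risk states carry less tree-like structure than a Brownian
trait would.

The same pipeline runs from the shell, either stepwise (`riskevo trees
consensus`, `riskevo trees date`, `riskevo code`, `riskevo dtt`,
`riskevo fit`, `riskevo simulate`) or end to end:

```bash
riskevo run --config run.yaml   # trees -> dating -> coding -> DTT -> fits
```

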