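# cultrait

Phylogenetic comparative methods for discrete cultural traits, built around
the question of how the elements of hunter-gatherer religiosity (animism,
belief in an afterlife, shamanism, ancestor worship, high gods and their
"active" variants) evolved on a population-history tree.

The package implements the full workflow of a discrete-trait cultural
phylogenetics study:

- **Supertree construction** — matrix representation with parsimony (MRP):
  Baum–Ragan coding of source trees with semi-rooted treatment of unrooted
  sources, an up-weighted linguistic "scaffold" acting as a topological
  constraint, a heuristic weighted-parsimony search (random addition + SPR +
  parsimony ratchet), and a semi-strict consensus.
- **Time calibration** — minimum node-age constraints in kya enforced on the
  supertree, with the remaining node heights interpolated between fixed
  anchors ("arbitrary ultrametricization", even or branch-length-proportional
  spacing).
- **Ancestral state reconstruction** — Fitch parsimony with exact
  most-parsimonious state sets and homoplasy indices (CI = m/s,
  RI = (g−s)/(g−m), per character and ensemble), and maximum likelihood under
  the two-state Mk1 model of Lewis (2001),
  P(change) = ½(1 − e^(−2qt)), with marginal ("proportional") state
  likelihoods per node, a likelihood decision threshold *T* (T = 2 ⇔ support
  ratio e² ≈ 7.4), and an asymmetric-rates likelihood-ratio test.
- **Correlated evolution** — Pagel's (1994) test: an independent 4-rate model
  versus a dependent 8-rate model on the joint 4-state chain of a character
  pair, with LR = ln L_d − ln L_i calibrated by Monte Carlo simulation under
  the fitted independent model.
- **Synthetic data** — Yule trees scaled to a target depth and binary
  characters whose stationary frequencies match target prevalences, so every
  stage is testable end to end; plus a bundled synthetic 33-society example
  dataset (see `cultrait.datasets`).

Estimation follows the statsmodels idiom: model objects
(`MkAncestralStates`, `PagelCorrelation`, `FitchParsimony`, `MRPSupertree`)
are constructed from data and `fit()` returns a results object with
estimates, diagnostics and a `summary()`.

## Worked example

```python
from cultrait import MkAncestralStates, PagelCorrelation, load_study_fixture

tree, matrix, _ = load_study_fixture("shallow")   # 33 societies + outgroup

asr = MkAncestralStates.from_matrix(tree, matrix, "animism").fit(threshold=2.0)
root = asr.ingroup_root("Outgroup")
print(f"P(present at LCA) = {root['p_present']:.4f}  significant: {root['significant']}")

pair = PagelCorrelation.from_matrix(tree, matrix, ("afterlife", "shamanism"))
fit = pair.fit(n_starts=2, seed=1).monte_carlo(n_sim=199, seed=1)
print(f"lnL_i = {fit.logL_i:.2f}  lnL_d = {fit.logL_d:.2f}  "
      f"LR = {fit.lr:.2f}  p = {fit.pvalue:.3f}")
```

Output:

```
P(present at LCA) = 0.9989  significant: True
lnL_i = -29.33  lnL_d = -19.97  LR = 9.36  p = 0.005
```

Animism — present in every sampled society — reconstructs as ancestrally
present at the last common ancestor of the societies with proportional
likelihood 0.999, clearing the T = 2 decision threshold. For afterlife ×
shamanism the dependent model improves the log-likelihood by 9.36 units,
and only ~0.5 % of datasets simulated under the fitted independent model
produce as large an improvement, so the two traits' evolution is
significantly coupled on this tree.

The full workflow (both date sets, all character pairs, report tables) is
one call — `cultrait.run_full_analysis({...})` — or, from a shell:

```bash
cultrait run --n-sim 199 --seed 1 --outdir results/
cultrait asr --character animism --dates shallow
cultrait pagel --pair afterlife,shamanism --nsim 199
```

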