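# Methods

This note documents the models, conventions and numerical choices behind
`cultrait`, and what the bundled synthetic data can and cannot establish.

## Trees, ages and calibration

Trees are rooted and may be multifurcating; ages are in kya, increase
root-ward, and satisfy `age(parent) − age(child) = branch length`. All
sampled societies are extant, so leaves sit at age 0.

Calibration uses minimum node-age constraints only (no confidence
intervals, no molecular dating). `enforce_min_node_ages` pins each
constrained clade's MRCA at `max(current age, minimum)` and propagates
root-ward so no parent is younger than a child; a clade specifier whose
MRCA contains extra leaves is rejected as non-monophyletic.
`ultrametricize` then places every unconstrained internal node strictly
between its nearest fixed ancestor and its oldest fixed (or leaf)
descendant. The default rule spaces the nodes of each intervening chain
evenly: a node whose longest free chain to the fixed frontier contains
`k` nodes (itself included) is placed at `floor + (ancestor − floor)·k/(k+1)`.
This is deterministic and reproduces the intuitive behaviour on
caterpillars (root at 12 over two free nodes → 8, 4). The original
"arbitrarily ultrametricize" operation of the GUI tool it emulates is
undocumented, so even spacing is this package's own, stated convention;
a `proportional` mode interpolating by the original branch lengths is
available behind a flag. Equal fixed ages on an ancestor–descendant pair
produce zero-length branches rather than an error; a fixed descendant
*older* than a fixed ancestor is an error.

## Character matrices

States are small integers: binary {0, 1}, SCCS-style graded {1..4}, `?`
missing. Graded ancestor-worship and high-gods variables are recoded to
nested binaries: *present* ⇔ state ≥ 2, *active* ⇔ state ≥ 3, so active ⇒
present row-wise. This mapping is chosen because state 1 codes absence and
state 2 codes "present but inactive in human affairs"; it reproduces the
nested prevalence pairs (45/24 and 39/15 percent) of the sample the
package was designed around. Prevalences are percentages of scored ingroup
taxa in state 1, missing cells excluded from the denominator, rounded
half-up to whole percent for reporting. A hypothetical outgroup scored 0
for every character can be attached once; attaching twice is an error.

## MRP supertrees

Baum–Ragan coding: every non-root internal node of every source tree
yields one binary character (descendants 1, the source's other taxa 0,
taxa absent from the source `?`). Semi-rooted coding scores the
hypothetical all-zero outgroup 0 for rooted sources and `?` for unrooted
ones; for unrooted sources, complementary splits are collapsed to one
character, oriented so the side holding the lexicographically smallest
taxon is state 1. Scaffold groupings (a tree or a ready-made character
block) enter as ordinary characters at a large weight — 100 in the study
protocol — implemented as weight multipliers rather than duplicated rows
(identical arithmetic, less memory).

Tree length is weighted Fitch length. At a possibly multifurcating node
whose children resolve to n₀ sets {0} and n₁ sets {1} (ambiguous {0,1}
children ignored), `min(n₀, n₁)` steps are added and the node takes the
majority set — exact for binary characters, verified against exhaustive
minimisation in the tests.

The search is random-addition stepwise insertion followed by SPR
hill-climbing (first improvement, seeded random visit order; SPR subsumes
NNI) and parsimony-ratchet cycles (a random ~25 % of characters
temporarily up-weighted ×3). The proprietary "new technology" heuristics
of TNT (sectorial searches, tree fusing, drifting) are not reproduced;
the implemented search matches exhaustive enumeration on 8-taxon problems
in the acceptance tests, and full-scale (hundreds of taxa) searches are
out of scope. All equally best distinct topologies found are retained
(deduplicated by split sets) and summarised by a semi-strict
(combinable-component) consensus: every clade present in at least one
best tree and contradicted by none.

## Parsimony reconstruction and homoplasy

Step counts and most-parsimonious state sets come from min-cost dynamic
programming over unordered costs (exact on multifurcations and with
missing data), with an up-pass giving, at every node, exactly the states
that occur in at least one most-parsimonious labelling. Equivocal nodes
are reported as state sets.

CI = m/s and RI = (g − s)/(g − m) with m = observed states − 1, s =
realised steps, g = minority-state count (the star-tree maximum).
Ensemble values sum m, s, g over characters; constant characters (m = 0)
are excluded from the ensemble by default — a documented convention, since
they would inflate CI without carrying signal — and RI is reported as
missing when g = m (autapomorphies). The all-zero outgroup row is included
by default (it polarises the characters); `include_outgroup=False` gives
the ingroup-only sensitivity analysis.

## Mk likelihood reconstruction

The two-state Mk1 model has one rate q for gains and losses; transition
probabilities use the closed form P(same) = ½ + ½e^(−2qt) (the asymmetric
2-rate generalisation uses the analogous analytic form; both are verified
against the matrix exponential to 1e−12). Rates are bounded to
[1e−8, 1e3] /kya and optimised on the log scale — bounded scalar
minimisation for Mk1, multi-start (3 seeded starts) L-BFGS-B for the
asymmetric model to avoid boundary traps.

Root priors: uniform for Mk1 (its stationary distribution); the
asymmetric model defaults to its stationary distribution with uniform as
an option. Ancestral states are marginal posteriors from the up-down
algorithm, reported as proportional likelihoods (normalised to sum to 1
per node). A node is flagged significant when the log-likelihood
difference between states reaches the decision threshold T; T = 2
corresponds to a support ratio of e² ≈ 7.389 ≈ 7.4. "Equivocal" means the
T rule fails in both directions. The asymmetric-rates LRT compares the
2-rate model against Mk1 (both with uniform root priors so the models
nest exactly) with 2·ΔlnL against χ²(1) at α = 0.05.

The "LCA of the sampled societies" reported throughout is the ingroup
root — the child of the global root on the other side of the outgroup
branch — matching the quantity of interest in ancestral-religion studies.

## Correlated evolution (Pagel 1994)

Joint states are numbered 1=(0,0), 2=(0,1), 3=(1,0), 4=(1,1).
The independent model has four rates (gain/loss of each trait); the
dependent model gives the eight single-step transitions their own rates;
double transitions have rate 0. The root prior over the four joint states
is uniform (the source studies do not state theirs); under independence
with a uniform prior the joint likelihood factorises into the two
single-trait likelihoods, which is both a tested identity and the fast
path for fitting the independent model.

LR is reported as the raw difference lnL_d − lnL_i, the convention used
in the literature this package targets (their printed LR values equal the
printed log-likelihood differences); 2·LR is also provided. The
dependent-model optimiser always includes the independent MLE (embedded
in the 8-rate parameterisation) as a start, so lnL_d ≥ lnL_i up to
optimiser tolerance on every dataset. The optimiser iteration cap
defaults to 500, mirroring the study protocol's "500 iterations";
gradients are forward differences batched into one objective call, which
keeps the Monte Carlo refits cheap.

The Monte Carlo p-value simulates `n_sim` datasets under the *fitted*
independent model, refits both models to each with the same optimiser
protocol as the observed fit, and reports
p = (1 + #{LR_sim ≥ LR_obs}) / (n_sim + 1). The +1 pseudo-count keeps
p bounded away from 0 (p = 0 is impossible under resampling); whether LR
or 2·LR is compared against the null is immaterial because the
transformation is monotone. Null simulation uses exact branch-wise
transition sampling for the two independent chains; general (dependent)
simulation uses Gillespie waiting times on the 4-state chain.

## Synthetic data

`simulate_tree` draws pure-birth (Yule) trees conditioned on the tip
count, extends all terminal branches by the waiting time to the next
(censored) birth so no terminal branch is zero, and rescales to a target
depth (default 33 taxa, 65 kya — the scale of a shallow-calibrated global
forager sample). `simulate_matrix` evolves each character under a 2-state
chain whose stationary frequency equals the target prevalence: with rate
scale r (default 0.02/kya, a handful of expected changes per character on
the default tree) the rates are q01 = r·p, q10 = r·(1−p), root state
drawn from the stationary distribution, so expected tip prevalence equals
p analytically — no tuning loop is needed. Targets of 1.0 are clipped to
0.995 so both rates stay positive. Dependent pairs evolve under an
explicit 4-state generator.

What the simulations emulate: tree shape and depth, trait prevalences,
rate magnitudes, and (optionally) trait coupling. What they do not:
horizontal transmission/borrowing between societies, geographic
autocorrelation, observation/coding error, and non-stationary rates.
Passing tests therefore certify the estimators under the assumed Markov
model, not the robustness of substantive conclusions to model violation.

## The bundled example dataset

The packaged 33-society dataset (`cultrait.datasets`, files prefixed
`synthetic_`) is a *constructed stand-in*, not a transcription of any
archived study data: per-society codings and node dates were invented to
match published summary structure — the seven prevalences
(100/79/79/45/24/39/15 %), a fully resolved topology with the deep
African/non-African split, Vedda as the deepest non-African lineage, the
Australian, East Asian and Beringian-American groupings, shamanism
without afterlife in one Na-Dene society, joint losses in two South
American societies, and active ancestor worship concentrated in
circumpolar societies. Two date sets are provided: "deep" (molecular-style
older minima, ingroup root ≥ 120 kya) and "shallow" (minimum-style dates,
ingroup root ≥ 65 kya, out-of-Africa ≥ 60 kya), the latter being the
default for correlation analyses. File integrity is checked by SHA-256 at
load time. Quantities that depend on the individual codings (ensemble
CI/RI, fitted rates, likelihood ratios) are therefore internally
reproducible but not comparable to any published per-dataset values;
prevalence-level quantities are.

## Problem sizes and defaults in the test battery

Acceptance-grade checks run at sizes where exhaustive oracles are exact:
pruning vs. enumeration at ≤ 6 leaves (1e−10), Fitch vs. enumeration at
≤ 7 leaves, search vs. all 10,395 8-taxon topologies. Operating
characteristics use 200 outer replicates × 99 null simulations on a
16-taxon tree for type-I error (band [0.01, 0.10] at α = 0.05, the
two-sided binomial range around the nominal rate), 10 replicates at 100
taxa for power (≥ 0.8 under a 20× gain-rate asymmetry), and 100 datasets
of 150 taxa for rate recovery (median relative error ≤ 0.3). Monte Carlo
refits inside these studies use a single optimiser start initialised at
the embedded independent MLE with a capped evaluation budget — the same
protocol for observed and simulated fits, so the comparison is exchangeable.

## Known limitations

- No Sankoff (weighted) parsimony, Dollo models, rate heterogeneity
  across branches, covarion/hidden-rate models, or > 2-state Mk.
- The MRP search is not a TNT replacement; it is validated only at small
  taxon counts and is quadratic-ish per SPR sweep.
- Monte Carlo p-values inherit the resolution 1/(n_sim + 1).
- Bootstrap/jackknife supports and multiple-testing corrections across
  the 21 character pairs are intentionally not applied (the workflow
  reports uncorrected per-pair p-values).
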