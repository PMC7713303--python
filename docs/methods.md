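# Methods

This note documents the models, conventions, numerical choices and known
limitations of `islandtraits`, in the spirit of a statistical-methods
appendix. Everything quantitative stated here is recomputed by the test
suite or by `scripts/acceptance.py`; nothing is asserted from memory.

## Trees and tree algebra

Trees are rooted, with branch lengths in Myr, stored as flat arrays in
deterministic postorder (children in parsed order; the root is the last
node). Edge *e* is identified with the postorder id of its child node, and
this ordering is what makes ridge-regression rate vectors comparable across
runs. Three matrices drive everything downstream: the patristic distance
matrix **D**, the shared root-to-MRCA time matrix **S** (diagonal = tip
depths), and the tips-by-edges path matrix **L** with L[i,e] = length of e
if e lies on the root-to-tip-i path. Invariants used as internal oracles:
row sums of **L** are tip depths; D[i,j] = Σₑ|L[i,e] − L[j,e]|; on
ultrametric trees D + 2S = 2T.

Ultrametricity is declared at a relative tolerance of 1e-3 by default —
time-calibrated trees distributed as Newick text routinely carry rounding
of that order — and the OU/EB machinery refuses non-ultrametric trees
unless forced. Zero-length branches are legal; negative lengths and
missing branch lengths are hard errors (no silent defaults). Multifurcating
nodes pass through every algorithm unchanged; nothing binarizes.

Taxon matching between trees and tables normalizes labels by trimming,
collapsing whitespace, and treating underscores as spaces, case preserved.
Unmatched names are reported and dropped, never fuzzy-matched.

## Trait-evolution models

All four models are Gaussian on the tip vector, which is what makes a
dense multivariate-normal evaluation and an O(n) pruning evaluation both
possible; their agreement (they are algorithmically independent — one
builds the covariance from the S/D formulas, the other runs contrasts on a
depth-rescaled tree) is asserted to 1e-8 in the tests, applied relatively
when |lnL| exceeds 1 because double precision caps absolute agreement near
1e-12·|lnL| at extreme shape parameters.

The OU variant is *non-stationary with the root fixed at the optimum*:
a single mean parameter z₀ ≡ θ, giving k = 3 parameters (σ², α, z₀). This
choice is forced by the parameter counts of the published comparison table
the package reproduces (3 for OU and EB, 2 for BM and WN). On an
ultrametric tree this OU covariance is a monotone time-warp of the node
depths, g(t) = e^(−2αT)·(e^(2αt) − 1)/(2α), which is how the pruning route
handles it; EB warps by g(t) = (e^(a·t) − 1)/a. Both warps are evaluated
with `expm1`, so the α→0 / a→0 limits degrade gracefully to BM.

Fitting profiles the mean and σ² analytically given the shape parameter
(GLS mean, ML variance = quadratic form / n), leaving a one-dimensional
bounded search: α ∈ [1e-8/T, 50/T] on a log grid, a ∈ [ln(1e-5)/T, 0]
linear, 5 starts each, the best three refined by bounded scalar
minimization. n in AICc is the number of tips with data on the pruned
tree. Ties in model selection go to the smaller AICc, then fewer
parameters, then the fixed order BM, WN, OU, EB. Akaike weights use the
max-subtraction trick.

Two model-selection caveats worth knowing. First, at its upper α bound the
OU covariance is close to diagonal, i.e. nearly white noise; on WN-simulated
data OU therefore attains at least WN's likelihood and occasionally wins
the strict AICc argmin with a ΔAICc under 2. The package's reporting
convention follows the source analysis — a model is *the* selected model
when its Akaike weight rounds to 1 and every competitor has ΔAICc > 2;
competitors within 2 units are listed as co-supported. Second, EB fits on
empirical-scale data typically run into the a = 0 boundary and collapse to
BM lnL; the bound ln(1e-5)/T (rate decayed to 1e-5 of its initial value
across the tree) is this package's choice, documented here because other
implementations bound differently.

## Phylogenetic GLS

The Brownian correlation is **S** scaled to unit tree height, with no
signal parameter estimated (fixed Brownian covariance, matching the
`corBrownian` convention of the source analysis). Estimation whitens with
the lower Cholesky factor and solves least squares on the whitened system;
no explicit inverse is ever formed. Rank-deficient designs fail with the
aliased columns named. Widespread species are excluded from every
habitat GLS fit (they are retained inside clades for model fitting, where
the clade, not the habitat label, is the unit).

Post-hoc contrasts run only when the habitat F test is significant at the
configured level (default 0.05), mirroring conditional HSD usage. The
multiplicity adjustment is single-step max-|t|: the joint null distribution
of the three pairwise contrast statistics is sampled (50,000 seeded draws
from the multivariate t implied by the contrast covariance; SVD
factorization because the contrast set is linearly dependent) and each
contrast's adjusted p is the exceedance probability of its |t|. Exact
studentized-range theory does not transfer to GLS with unequal
correlations, so this Monte-Carlo analogue stands in for Tukey's HSD;
Holm's step-down is available as a deterministic fallback. The compact
letter display labels maximal cliques of the non-significance graph,
ordered by fitted group means — a deterministic function of the
significance matrix.

The trait–trait correlation is a GLS correlation of the two centered,
whitened trait vectors, with df = n − 2. "Best-fitted covariance" is
resolved by comparing BM against OU (each trait fitted under both, summed
AICc); under OU the correlation matrix uses the mean of the two per-trait
ML α values. The slope standard error reported alongside r is the SE of
the GLS regression slope of y on x.

## Ridge-regression rates and the shift test

The rate model writes each tip as root state plus Σ (branch length ×
branch rate) along its path; with 2n−2 edges against n tips the system is
always underdetermined, hence the ridge penalty on the rates (the root
state is unpenalized). The solution comes from the augmented normal
equations; ancestral states accumulate length×rate down each path and
satisfy that identity to machine precision (asserted at 1e-10).

λ is selected by generalized cross-validation: the intercept is profiled
out by centering, the centered path matrix is SVD-factored once, and
GCV(λ) = n‖r(λ)‖²/(n − 1 − tr H(λ))² is minimized over a log-spaced
25-point grid spanning [1e-6, 1e2]× the largest squared singular value,
refined by golden-section search on log λ. Deterministic; exact ties go to
the smallest λ; a flat objective (constant trait) returns the grid minimum
with a warning. The original published routine's internal penalty objective
is not documented in the source analysis, so GCV is this package's own,
stated choice; numerical agreement with the published rate table is not
claimed (and would require the original data regardless).

The per-tip rate statistic is the absolute value of the standardized
(zero-mean, unit-SD) terminal-edge rate; a path-averaged alternative is
available behind a flag. For each habitat the observed statistic is the
mean tip rate in the habitat minus the mean outside it, and p is the
fraction of label permutations with a difference at or below the observed
one — so p > 0.975 means increased rates, p < 0.025 decreased, anything
between no difference, exactly the two-tail convention of the published
rate table. Pairwise habitat tests restrict to the two states' tips. No
multiplicity correction is applied across states (raw per-state p values
are reported, as in the source). Permutations are vectorized, seeded, and
invariant to tip ordering (tips are sorted by normalized label before
permuting). The published routine's node-wise "clade" mode is out of
scope; only the state (habitat) mode is implemented.

## PhyloSor partition

Edge presence is evaluated against the root of the full supplied tree
(root path included): this makes the additive partition exact and the
star-tree case reduce to classical species-level Sørensen. An `mrca_only`
flag instead prunes each pair to the MRCA of their union, since published
usage is ambiguous on this point; the full-tree convention is the default.
β_sor = β_sim + β_sne holds to 1e-12 by construction and is asserted over
random assemblage pairs. Widespread species are excluded before
assemblages are formed (a flag re-admits them for exploration).

## Synthetic-data generator

The generator is first-class, tested code: birth–death trees conditioned
on the number of extant tips by forward event simulation (the present is
set one exponential waiting time after the count is reached; extinct
lineages are pruned; failed runs are retried up to 10,000 times), traits
by root-to-tip recursion under any of the four models (true node states
are returned for recovery tests), habitat labels either i.i.d. or in
whole-clade blocks (the latter generating the phylogenetic clustering that
makes beta-diversity turnover non-trivial), additive per-habitat trait
shifts, per-habitat terminal-edge rate multipliers (the multiplier scales
the SD of the terminal-edge increment; a flag extends multipliers to whole
clades), and a configurable widespread fraction. Randomness is NumPy
PCG64; a scenario seed is split with `SeedSequence.spawn` into independent
tree / habitat / trait / widespread streams, so outputs are reproducible
bit-for-bit and stage-by-stage.

Default scenario: 150 tips, speciation 0.1/Myr with no extinction (tree
height of order 50 Myr), an OU trait with σ² = 0.02 log₁₀-units²/Myr,
α = 0.05/Myr and optimum 0.8 (≈ 6 m stem height on the log10 scale),
habitat probabilities 0.5/0.3/0.2 (mainland most frequent). Simulation
studies in the tests use 100–200 tips — desk-scale analogues chosen so the
whole suite exercises every stage, not the 2,500-species scale of a real
family-wide phylogeny.

What the generator does *not* emulate: taxonomic name noise (labels match
exactly), missing-data structure correlated with clades or habitats,
measurement error in traits, posterior samples that share a topology
distribution (the "posterior" stand-in is independent replicate trees with
the same labels — fine for sensitivity machinery, wrong for inferences
about actual topological uncertainty), and trait-dependent
diversification. Passing tests therefore demonstrate correctness of the
estimators and calibration of the tests under the stated generating
models, not robustness to those real-data complications.

## Pipeline

One YAML config drives classification → GLS → model selection → rate
shifts → beta diversity → sensitivity, in that order; every artifact is
CSV/JSON with floats printed at 10 significant digits, and identical
config + seeds reproduce every CSV byte-for-byte (asserted in the tests).
The log records input SHA-256 hashes and the seed; its timestamp line is
the only non-reproducible output. A stage failure writes
`failure_manifest.json` and aborts with the stage named; completed
artifacts are left in place.

## Known limitations

- Single-optimum OU only; no multi-regime (OUwie-style) models, no
  measurement error, no Pagel transforms.
- The GLS assumes the fixed Brownian correlation; no λ/κ/δ estimation.
- GCV-selected ridge penalties differ from the original published rate
  routine by construction (see above).
- Habitat classification consumes pre-built occurrence/realm tables;
  nothing here resolves names or geology.
- O(n²)–O(n³) dense linear algebra throughout: comfortable to a few
  thousand tips, not beyond.
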