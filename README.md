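# islandtraits

Phylogenetic comparative analysis of plant trait evolution across mainland,
continental-island and volcanic-island habitats.

Island floras are natural experiments in trait evolution: geographic
isolation relaxes interspecific competition and opens ecological
opportunity, so island lineages are often expected to evolve key
life-history traits — plant height, fruit/seed size — faster than their
mainland relatives, or to show early-burst signatures of adaptive
radiation. `islandtraits` packages the full analytical chain needed to test
those expectations on a time-calibrated species-level phylogeny plus trait
and occurrence tables, and ships seeded synthetic-data generators so every
stage can be exercised and power-tested without any external dataset.

## What it computes

**Habitat classification** (`trait_data`). Species are assigned to
mainland / continental island / volcanic island from occurrence records in
geographic units; species spanning more than one category are *widespread*
and excluded from the main analyses. Classification is done globally and
within each biogeographical realm (Afrotropics, Australasia/IndoMalaya,
Neotropics; Hawaii is analyzed with the Neotropics). Traits (maximum stem
height, fruit diameter) are log10-transformed.

**Trait-evolution model selection** (`evomodels`). Four Gaussian models of
a trait *x* on a tree with shared-time matrix **S** and patristic distances
**D**, compared by AICc and Akaike weights:

- **BM**: x ~ N(z₀·1, σ²·S)
- **OU** (root at the optimum): Cov[i,j] = σ²/(2α)·(1 − e^(−2α·Sᵢⱼ))·e^(−α·Dᵢⱼ)
- **EB**: BM with rate decaying as e^(a·t), a ≤ 0 (branch over root-times
  [t₁,t₂] gets length (e^(a·t₂) − e^(a·t₁))/a)
- **WN**: i.i.d. N(μ, σ²), no phylogenetic structure

Each likelihood has a dense matrix route and an O(n) pruning route that
must agree; z₀/μ and σ² are profiled analytically, the OU/EB shape
parameter is optimized by a bounded multi-start search. AICc = −2lnL + 2k +
2k(k+1)/(n−k−1) with k = 2 (BM, WN) or 3 (OU, EB).

**Phylogenetic GLS** (`pgls`). y = Xβ + ε with ε ~ N(0, σ²C), C the
Brownian correlation (shared times scaled to unit height), solved by
triangular whitening — with C = I everything reduces exactly to OLS/ANOVA.
Includes nested-model F tests, all-pairs habitat contrasts with a
single-step max-|t| adjustment (the GLS analogue of Tukey's HSD; seeded
Monte-Carlo, Holm fallback), compact letter displays, a GLS trait–trait
correlation with BM-vs-OU structure selection, and sensitivity summaries
across posterior tree samples.

**Rate shifts** (`rate_shift`). Phylogenetic ridge regression: tip values
are regressed on their root-to-tip branch paths, min ‖x − m·1 − L·β‖² +
λ‖β‖², giving one signed rate per branch and ancestral states; λ is chosen
by GCV. Standardized absolute terminal-edge rates per habitat are compared
to the rest of the phylogeny (and between habitat pairs) by label
permutation; p > 0.975 flags increased and p < 0.025 decreased rates.

**Beta diversity** (`beta_div`). PhyloSor dissimilarity between habitat
assemblages from shared (a) and unique (b, c) branch lengths,
β_sor = (b+c)/(2a+b+c), additively partitioned into turnover
β_sim = min(b,c)/(a+min(b,c)) and nestedness β_sne = β_sor − β_sim.

**Synthetic data** (`synthetic_data`) and **pipeline** (`pipeline`, CLI
`islandtraits`). Seeded birth–death trees, traits under all four models,
habitat scenarios with additive shifts and terminal-edge rate multipliers,
and a config-driven end-to-end run producing CSV artifacts.

## Worked example

Run the pipeline on a bundled synthetic scenario — 80 species, a pure-birth
tree, an OU trait in log10 units, and a +0.3 log-unit height shift on
volcanic islands:

```sh
cat > cfg.yaml <<'EOF'
output_dir: out
seed: 3
scenario:
  n_tips: 80
  seed: 3
  trait_shift: {volcanic_island: 0.3}
  widespread_fraction: 0.1
n_posterior: 5
n_perm: 300
EOF
islandtraits run --config cfg.yaml
islandtraits report --bundle out
```

prints (abridged):

```
Model selection (AICc):
  log_fruit_diameter: supported model(s) OU
  log_height: supported model(s) OU

pGLS habitat effects:
  log_fruit_diameter: F_2,69 = 2.065, p = 0.1346, n = 72
    no significant habitat effect; contrasts not run
  log_height: F_2,69 = 11.585, p = 4.59e-05, n = 72
    mainland - continental_island: -0.035 (p_adj = 0.864)  letters a/a
    mainland - volcanic_island: -0.301 (p_adj = 2e-05)* letters a/b
    continental_island - volcanic_island: -0.266 (p_adj = 0.00234)* letters a/b
```

Read: both traits were simulated under constrained (OU) evolution and the
AICc table recovers that; the habitat F test finds the height shift
(n = 72 after dropping widespread species), the Tukey-style contrasts
attribute it to volcanic islands (−0.301 ≈ the planted −0.3 seen from the
mainland side), and the letter display separates volcanic (`b`) from the
other two habitats (`a`). The fruit trait, simulated with no habitat
effect, shows none. The bundle also contains `table1.csv` (the AICc
table), `table2_rates.csv` (rate-shift verdicts), `fig1c_beta.csv`
(PhyloSor partitions per realm) and `sensitivity.csv` (pGLS spread across
posterior trees).

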