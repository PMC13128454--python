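# Methods

## Trapping model

The kinetic module models a bifunctional small molecule that crosses the cell
membrane freely and binds a single intracellular target protein. Assumptions:

- the extracellular reservoir is large, so `[M_A]` is constant (`d[M_A]/dt = 0`);
- membrane transport is first-order and symmetric with rate `k_diff`, so free
  compound equilibrates toward `[M_B] = [M_A]` in the absence of binding;
- one binding partner dominates trapping (the abundant target); binding of the
  toxin's own target is neglected — no ternary-complex occupancy model is
  attempted because none is specified by the underlying science;
- the complex `MP` is degraded at the protein's first-order rate `ln2/t½`
  (compound-bound protein is turned over like free protein); the released or
  co-degraded compound is not returned to the free pool, and intracellular
  free compound itself has no degradation or efflux term;
- the protein is produced at a constant rate `r_prod`, calibrated **once**
  from a reference steady state (`P_ss_ref = 1 µM` at `t½_ref = 24 h`,
  giving `r_prod = P_ss_ref·ln2/t½_ref ≈ 8.02e-12 M/s`) and then held fixed
  for every simulated half-life. This is deliberate: it encodes "same
  synthesis, slower degradation", so a 17 h protein reaches a ~64× larger
  pool than a 16 min protein. `KineticParameters.with_()` permits explicit
  recalibration if a caller wants the alternative convention.

Default constants (seconds/molar internally): `k_diff = 1e3 /s`,
`k_bind = 8.7e5 /M/s`, `k_unbind = 1e-6 /s`, initial state
`(M_A0, 0, 1e-6 M, 0)`.

### Numerics

`k_diff = 1e3 /s` against hour-scale turnover makes the system stiff
(rate-scale ratio ~1e7), so `simulate` uses `scipy.integrate.solve_ivp` with
the implicit BDF method and an analytic Jacobian, `rtol = 1e-8`,
`atol = 1e-15 M` (states span pM–µM). Output is 200 log-spaced time points
prepended with t = 0; the endpoint is the integrator's final state, never an
interpolation. Integration runs to 600 h, ≥ 8.7 half-lives past the slowest
tested mode (48 h), so the endpoint sits within ~0.01% of steady state.
States are clipped at zero to remove sub-`atol` solver noise.

### Closed-form oracle

Setting the derivatives to zero gives `P + MP = r_prod/λ` (λ = ln2/t½),
`k_bind·M_B·P = MP·(k_unbind + λ)` and `M_B = M_A − MP·λ/k_diff`, which
reduce to a quadratic in `MP`. `steady_state_closed_form` solves it with the
numerically stable quadratic formula, selects the physically admissible root
(`0 ≤ MP ≤ r_prod/λ`, `M_B ≥ 0`) and verifies the residual derivatives
vanish. Degenerate cases (`k_bind = 0`, `M_A = 0`, `r_prod = 0`) reduce to
the diffusion-only equilibrium. The tests require numeric-vs-analytic
agreement within 0.1% per nonzero component over a 20-point grid spanning
half-lives of 10 min–48 h and doses of 1e-11–1e-7 M.

An infinite half-life (λ = 0) is not representable: a nonzero production
rate then has no steady state, and the constructor requires `t_half > 0`.

## Differential screens

Score matrices are samples × features with NaN for missing values; samples
carry a TP53 status from {WT, missense, truncating, other}. "Mutant"
defaults to every non-WT status; a missense-only contrast is available via
`mutant_def`. Choices:

- the t-test is **Welch** (unequal variance), two-sided, because the
  emulated panels have unbalanced group sizes; Student's variant is a flag;
- q-values are Benjamini–Hochberg across all *tested* features; features
  with < 2 non-missing observations in either group are excluded from
  testing (NaN p and q) rather than imputed;
- missing values are dropped per feature per group; group means over an
  empty group are NaN, never zero;
- hit rules: dependency `mean_mut < −0.5 ∧ delta < −0.2` (strict), sorted by
  delta ascending; proteomics `delta > 2 ∧ q < 0.05`, sorted by delta
  descending. An empty hit list is a meaningful outcome, not an error —
  on real TP53 panels it is the observed one for dependencies.
- an optional `feature_subset` (e.g. a surface-protein list) restricts both
  testing and the multiplicity adjustment.

## Target nomination

Genes are inner-joined across the essentiality and abundance tables,
filtered to `mean_chronos ≤ −2` and `abundance ≤ 920 nM`, and ranked by
`score = log10(abundance_nM) + mean_chronos`, ascending. log10 is taken of
abundance **in nM** (the unit of the filter threshold); since a unit change
multiplies abundance by a constant, it shifts all scores equally and cannot
reorder — a property the tests verify. Ties break lexicographically by gene
id for determinism. Duplicate protein entries per gene must be
pre-aggregated by the caller; no symbol-alias resolution is attempted.

## cis/trans phasing

Alignments to a single transcript are grouped by read name; for each of the
two variant sites a pair contributes "ref"/"alt"/"other" (mates disagreeing
at a site are "other", conservatively) or "uncovered" (no mate aligns a base
there with quality ≥ 20). A pair is *informative* when both sites are
ref or alt. The call uses only alt-containing pairs — ref–ref pairs arise
from the non-variant haplotype in either configuration, so they count toward
coverage but are neutral:

- `cis` when alt–alt pairs are ≥ 90% of alt-containing pairs,
- `trans` when alt–ref plus ref–alt pairs are ≥ 90%,
- `ambiguous` otherwise, `insufficient` below 5 informative pairs.

The thresholds (`min_informative = 5`, `max_conflict = 0.1`, base quality
≥ 20) are this package's own defaults, chosen so that a 1% per-base error
rate on 100 pairs yields the correct call in ≥ 99% of replicates (verified
by simulation); all are configurable. Swapping the site labels exchanges
the two discordant counts and provably never flips cis vs trans; the tests
check this exhaustively for all count tables of up to 10 pairs.

## Dose–response conventions

- Responses are normalized to the mean vehicle (dose 0) response.
- Potency comes from a four-parameter logistic on log dose,
  `response = bottom + (top − bottom)/(1 + (dose/ec50)^hill)`, fitted by
  least squares in `log10(ec50)` with bounds two decades beyond the tested
  dose range, initialized from the extreme-dose means. Orientation is
  normalized after fitting (`bottom ≤ top`, direction in the sign of
  `hill`). A flat table returns `converged = False` with no EC50 — a
  potency is never fabricated. 4PL (free Hill slope) rather than 3PL/5PL:
  the extra asymmetry parameter of 5PL is not identifiable at 8-dose
  designs, and fixing the slope (3PL) biases EC50 when curves are steep.
- Emax is an **observed** extremum of per-dose means (replicates collapsed
  by mean, configurable to median), never a fit asymptote: the minimum for
  competition/viability readouts, the maximum for vehicle-normalized
  NanoBiT signal. Vehicle rows are excluded.
- qPCR relative expression is `2^−ΔΔCt` with ΔCt = Ct(target) − Ct(reference)
  per condition.

## Synthetic data

All generators draw from `numpy.random.default_rng(seed)` (PCG64); its
integer stream is platform-stable, so a seed plus a config reproduces
byte-identical outputs. Defaults encode the study conditions:

- **Panels**: 200 WT / 50 missense / 20 truncating samples, 2000 features —
  the mutant/WT imbalance of large cell-line panels.
- **Dependency**: per-gene baseline means ~ N(−0.3, 0.3), per-sample noise
  ~ N(0, 0.3) (a typical per-line Chronos spread); null by default. Planted
  synthetic-lethal effects add a group shift (e.g. −0.6 in mutants).
- **Proteomics**: unit-scale raw noise, z-scored per feature after
  planting. Planted shifts are specified in z-units *after* standardization;
  because standardization divides by the pooled SD, which the shift itself
  inflates, the raw shift is back-computed as
  `s = d·σ/√(1 − d²f(1−f))` for group fraction f — so a requested Δz = 2.5
  (the hit threshold of 2 plus margin) is what the screen actually sees.
- **Nomination**: decoy Chronos ~ N(−0.3, 0.4) — mean scores ≤ −2 are > 4σ
  events, matching how rare strongly essential genes are — and abundance
  ~ 10^N(2,1) nM (median 100 nM). Planted targets draw Chronos from
  (−3, −2.5) and abundance from (5, 50) nM.
- **Read pairs**: a 300 nt synthetic transcript with heterozygous variants
  at positions 100 (A>G) and 180 (C>T); each 80 nt mate pair is drawn from
  one of two haplotypes (cis or trans configuration), with uniform per-base
  miscalls at the configured error rate (default 1%). The truth table
  records the alleles actually emitted, so extraction must round-trip it
  exactly.
- **Dose–response**: 4PL truth (default EC50 25 nM, Hill 1, 0–100 range)
  on an 8-dose log grid, 3 replicates, Gaussian noise.

What the generators do **not** emulate: real Chronos score correlation
structure across genes, batch effects, copy-number confounding of
dependencies, proteomics missingness patterns, alignment artifacts (indels,
clipping, chimeric reads) or heteroscedastic assay noise. Passing tests
therefore demonstrate correctness of the statistics and decision rules under
their stated sampling assumptions, not robustness to every real-data
pathology.

## Problem sizes

The test suite and acceptance script run at the sizes the analyses are
designed for: 270-sample × 2000-feature panels over 20 seeds, a 10⁴-gene
nomination table, 100 phasing replicates of 100 pairs, 100 noisy EC50
recoveries, and a 20-point kinetic parameter grid — the whole suite
completes in well under a minute on one core.

## Known limitations

- The kinetic model ends at compound accumulation; there is no coupling to
  cell growth or death, and no ternary-complex model.
- The screen module assumes samples are independent; lineage structure in
  real panels would call for mixed models it does not provide.
- Phasing handles exactly two biallelic substitution sites on one
  transcript; it is not a general haplotyper and has no statistical model
  of switch errors.
- Reported EC50s are this package's 4PL convention; other fitting choices
  (3PL, constrained asymptotes) give systematically different values on
  shallow curves.
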