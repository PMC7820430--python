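# Methods

## The index model

The soil health index is a weighted additive index over a minimum data
set (MDS) of soil attributes,

    SHI = Σᵢ wᵢ · sᵢ ,

built per season (rainfed sorghum, saline-irrigated wheat) because the
two soil environments differ systematically in salinity, moisture and
temperature. The chain and its assumptions:

1. **Standardization.** The 14 attributes are column-standardized
   (mean 0, SD 1, n−1 denominator), so the PCA operates on the sample
   correlation matrix and attributes with large numeric ranges (e.g.
   NH₄OAc-K in kg/ha) do not dominate.
2. **PCA.** Eigendecomposition of the correlation matrix
   (`numpy.linalg.eigh`), eigenvalues descending. The loading sign is
   fixed by making each PC's largest-|loading| entry positive; this is a
   pure reporting convention that makes selections reproducible across
   eigensolvers and platforms.
3. **Retention.** Keep PCs with eigenvalue ≥ `eigen_min` (default 1.0)
   *and* variance share > `var_min` (default 0.05). `eigen_min` is
   configurable because common practice varies between "≥ 1" and
   "> 0.99"; both are expressible.
4. **Selection.** Per retained PC, take the attribute with the highest
   |loading| plus every attribute whose |loading| ≥ (1 − `within_frac`)
   × that maximum (default `within_frac` = 0.10, inclusive comparison;
   ties resolved by input attribute order). Attributes already chosen
   from an earlier PC are skipped in later ones. An optional
   redundancy rule (`redundancy_r`) prunes co-selected attributes within
   a PC correlated above the cutoff down to the highest-loading member;
   it is OFF by default, since index-construction practice commonly
   retains correlated co-selections.
5. **Scoring.** Linear min–max scoring onto [0, 1]:
   more-is-better s = (x − x_min)/(x_max − x_min), less-is-better
   mirrored, optimum as a symmetric tent around a midpoint. A ratio
   variant (x/x_max, x_min/x) is available behind
   `ScoringSpec(variant="ratio")` for sensitivity analysis. Default
   directions: EC_e and pH_s less-is-better; organic C, available
   N/P/K, microbial biomass and all enzyme activities more-is-better;
   the MBC:MBN ratio has no agreed orientation and defaults to an
   optimum at the data median — all overridable. Bounds default to the
   observed per-season min/max (so the scores span [0, 1] by
   construction); fixed bounds can be configured for cross-dataset
   comparability.
6. **Weighting.** wᵢ = (variance share of the indicator's source PC) ÷
   (cumulative share of all retained PCs). Every indicator selected
   from a PC receives that PC's full weight — the weight is not split
   among co-selected indicators — and normalization over contributing
   PCs is OFF by default. Published sorghum/wheat weight sets of this
   index family do not sum to 1, so the package does not force a
   normalization the method statement never makes; `normalize=True` is
   available.
7. **Index and downstream use.** SHI is computed per plot observation,
   so it can itself be analysed by the split-factorial ANOVA and
   separated with Tukey letters; treatment means are taken afterwards.
   Yield association is a one-predictor OLS (R² = 1 − SS_res/SS_tot).

## The split-factorial ANOVA

The design: tillage randomized to main plots within blocks; the
irrigation × mulch factorial randomized to subplots; the whole layout
repeated over years. The model treats **year as a crossed fixed
whole-plot factor** and **replication (block) as a fixed term**, which
reproduces the conventional printed skeleton exactly (with 3 blocks,
2 years, 3 tillage: whole-plot units = 18, whole-plot terms df
2+1+2+2 = 7, "Error (a)" df = 10; subplot residual df = 60; total 107).
No random-effects/REML machinery is used; year-to-year autocorrelation
is ignored by construction.

Sums of squares use the balanced-design decomposition: for term T,
SS_T = Σ_{U⊆T} (−1)^{|T|−|U|} R(U) with R(U) the uncorrected SS of the
U-margin cell means. Error (a) is the block×year×tillage margin SS minus
the whole-plot term SS (i.e. block interactions pooled); Error (b) is
the remainder. F-tests use Error (a) for replication, year, tillage and
year×tillage, Error (b) for every term involving irrigation or mulch.
Only complete balanced tables are accepted — imbalance is a hard error,
not an invitation to type-III machinery.

Mean separation: Tukey HSD with the stratum-appropriate error MS,
`HSD = q(1−α; k, df_err)·√(MS_err/n)`, where n counts all observations
behind a level mean (for whole-plot factors this counts subplot
observations, matching the single-letter main-effect displays of field
reports; configurable in principle via the function arguments). Compact
letters use the insert-and-absorb algorithm, letters assigned in
descending-mean order. Interaction cells are compared with Fisher's
LSD, `t(1−α/2; df_err)·√(2·MS_err/n)`. Significance stars follow the
*, **, *** at 0.05/0.01/0.001 convention with NS otherwise.

## The synthetic generator

The generator emulates the reference saline-field trial so that every
downstream stage is testable without field data. Per attribute and
observation:

    value = baseline + block intercept + year shift + Σ factor effects
            + λ·σ·z + σ·ε ,

with z a single standard-normal latent "plot salinity" per observation
and ε independent Gaussian noise.

- **Baselines and factor effects** for the chemical attributes (pH_s,
  EC_e, WBOC, KMnO₄-N, Olsen's P, NH₄OAc-K) are anchored to the
  published two-year treatment means of the reference trial, so the
  planted irrigation contrast on EC_e is 0.73 dS/m after sorghum and
  1.19 dS/m after wheat, mulch lowers wheat-season EC_e by ~0.57 dS/m,
  and reduced/zero tillage shift Olsen's P and NH₄OAc-K in the
  published directions. Effects are stored as deviations that sum to
  zero within each factor.
- **Microbial/enzyme baselines** are not published as tables; the
  defaults are field-plausible values chosen once (MBC 120/102,
  MBN 14.8/13.2 — putting MBC:MBN inside the reported 7.4–8.4 band —
  DHA, AlP, Ur, α-/β-glucosidase at typical assay magnitudes, with
  glucosidases higher after wheat), with directional treatment effects
  (deficit irrigation and mulch raise biomass/enzymes, zero tillage
  raises MBN, conventional tillage raises DHA/AlP after sorghum).
- **Residual SDs** are back-calculated from the printed standard errors
  of means (SD ≈ SE_m·√n with n = 36 behind a tillage mean); biological
  attributes use ~10–15 % CV. All config-overridable.
- **Coupling.** Loadings λ (in SD units): EC_e +0.8; MBC −0.45,
  MBN −0.50, DHA −0.50, β-glucosidase −0.45, with weaker loadings on
  Ur, AlP and α-glucosidase. The implied within-cell correlation is
  r_ab = λ_a·λ_b / √((1+λ_a²+f²)(1+λ_b²+f²)) (f = block-intercept SD
  fraction, default 0.3), which places corr(EC_e, ·) for the four
  coupled attributes in (−0.6, −0.2), matching the reported range of
  salinity–biology correlations. `ground_truth()` returns the exact
  effects and this implied matrix for recovery tests.
- **Yields** are linear in (attribute − baseline) deviations — dry
  fodder responds to EC_e and MBN; wheat grain to EC_e plus direct
  tillage/mulch effects (zero tillage penalised) — plus Gaussian noise.
- **MBC:MBN** is derived from the sampled MBC and MBN, never sampled.
- Sampled non-negative attributes are truncated at 0 with a logged
  count; default SDs keep truncation essentially absent.
- `SyntheticConfig.null()` zeroes every effect, shift and coupling for
  type-I-error simulation.

What the generator does **not** emulate: mechanistic salt/water
balance, weather, spatial autocorrelation within blocks, non-Gaussian
tails, season-to-season carry-over beyond a fixed year shift, and
missing data. Passing tests therefore demonstrate the statistical
machinery under the design and effect structure of the reference trial,
not robustness to those field realities.

## Numerical and testing choices

- Determinism: one `numpy` Generator seeded per call; identical
  config + seed gives bit-identical tables and byte-identical report
  bundles (the run manifest echoes config, seed and version; no
  timestamps are written).
- Studentized-range quantiles are cached by (confidence, k, df) —
  `scipy.stats.studentized_range.ppf` is expensive and the pipeline
  calls it with few distinct arguments.
- The MBC:MBN column is recomputed from MBC/MBN at validation and
  cross-checked against any supplied column at 1 % relative tolerance.
- Degenerate inputs fail loudly and early: constant columns in
  standardization/scoring, zero-variance SHI in regression, designs
  with an empty error stratum, unbalanced tables.
- The index-monotonicity property (lowering a plot's EC_e never lowers
  its SHI) holds under *fixed* scoring bounds and is tested that way;
  under observed bounds, changing one attribute moves the bounds of all
  plots and pointwise monotonicity is genuinely not guaranteed.
- Null-correlation checks on the generator run at 25 blocks (900 rows
  per season) rather than the 3-block field size, so the maximum over
  all ~80 attribute pairs has negligible false-alarm probability; the
  type-I-error suite runs 1000 simulated trials at the reference size
  (108 rows per season), which takes roughly half a minute.
- The MDS-recovery suite plants two orthogonal latent factors each
  driving an attribute pair with noise SD 0.35 (within-pair correlation
  ≈ 0.89), a structure strong enough that the within-10 % rule should
  recover all four attributes essentially always; 200 seeds, ≥ 95 %
  required.

## Known limitations

- Fixed-effects ANOVA only; no variance components, no repeated-measures
  correction, no unbalanced data.
- Exact reproduction of the reference trial's PCA loadings, variance
  shares and index values is impossible without its unpublished
  plot-level data; the package reproduces the pipeline's structure and
  the arithmetic of the published treatment means, and all statistical
  guarantees are demonstrated on the synthetic emulation.
- The weight rule is one member of a family used in the index
  literature; the printed weight sets it emulates cannot discriminate
  among all variants, which is why the rule, the eigenvalue threshold
  and normalization are all configurable.
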