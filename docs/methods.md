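# Methods

## Mass-balance model

Each plant is a closed three-compartment system at harvest: rosette, stem
(stem + cauline leaves + empty siliques) and total seeds. Roots are not
part of the model (they are lost at harvest in practice), so all indices
are aboveground quantities and no uptake-efficiency (NUpE) index is
offered.

Concentrations are percent of dry weight, so pools are true masses:
QtyN = DW·N%/100 (mg) and Qty¹⁵N = QtyN·E%/100 (mg of excess ¹⁵N). The
enrichment E% = A%_sample − A%_control uses a configurable natural-abundance
baseline (default 0.3660 atom %). E% may be slightly negative for
unlabelled tissue through measurement noise; raw E% values are reported,
but excess-¹⁵N pools are floored at zero before allocation fractions are
formed so the fractions always lie in [0, 1] and sum to 1.

Indices are computed **per plant and then averaged** (means of ratios).
This matches how replicate plants are summarised in practice and explains
why a population-mean NUE is not the ratio of mean NHI to mean HI.

Degenerate-seed guard: plants whose seed DW falls below `guard_dw_mg`
(default 1 mg — a near-sterile plant, not merely a small one) get NaN for
the seed-sink ratios NUE and NRE instead of near-infinite values; HI,
allocations and NHI are still computed, and the plants are counted
separately in summaries.

NUtE is defined as total aboveground DW over total aboveground N (mg/mg),
which for these plants is of order 25–45. Published values of a
same-named index are sometimes of order 0.4, implying different units;
this package documents its mg/mg convention and makes no attempt to match
other scalings.

## Orthogonal regression and ΔSC

The seed C%-vs-N% line is the **major axis**: the direction of the leading
eigenvector of the 2×2 covariance of (N%, C%), through the centroid. With
centred second moments S_nn, S_cc, S_nc the slope is

    b = (S_cc − S_nn + sqrt((S_cc − S_nn)² + 4·S_nc²)) / (2·S_nc),

computed in closed form. No standardisation is applied before fitting:
both axes are percentages of dry weight, and the trait is defined on the
raw scale. Reduced-major-axis (geometric-mean) regression is a different
estimator and is not what "minimises the sum of squared orthogonal
distances"; the major axis is implemented because that geometric
definition is the one the ΔSC trait depends on. Degenerate inputs are
refused loudly: fewer than 3 points, or isotropic scatter
(S_nc = 0, S_nn = S_cc), where the major-axis direction is genuinely
undefined and any tie-break would silently fabricate a trait. Exactly
horizontal or vertical lines are representable; ΔSC values against them
carry a flag because only one of the two gaps is finite.

ΔSC of a point (N₀, C₀) uses the two gaps to the line, DiffC = C₀ − (a + b·N₀)
and DiffN = N₀ − (C₀ − a)/b, combined as the altitude of the right triangle
they form:

    ΔSC = sign(DiffC) · |DiffN·DiffC| / sqrt(DiffN² + DiffC²),

which equals the signed perpendicular distance (C₀ − a − b·N₀)/√(1+b²)
identically — the package asserts this equivalence against the projection
formula in its tests rather than trusting the algebra. For negatively
sloped lines sign(DiffN) = sign(DiffC) always; when the two signs disagree
(possible only for positive slopes) the sign is taken from DiffC and the
value flagged.

Fit scope: one line per (experiment, condition), pooling all genotypes,
and each plant is scored against the line of its own stratum. A pooled
per-condition mode (`dsc_table(..., mode="pooled")`) is also exposed,
since either choice is defensible; the per-experiment default keeps
between-experiment line drift out of the trait.

Condition shifts are per-experiment deltas (slope and intercept of each
stress fit minus the same experiment's control fit), summarised as
across-experiment mean ± SD. Response vectors are genotype-wise (ΔN%, ΔC%)
displacements of seed-composition means from the control cell; a
condition is labelled *heterogeneous* when the circular standard
deviation of the vector angles exceeds 60° (a reporting threshold, chosen
so that roughly opposite-quadrant responses trip it; configurable).

## Variance components and heritability

Sums of squares for the three-way layout come from the classical
balanced-design cell-mean formulas; on balanced data they coincide with
every ANOVA type (the test suite checks them against an independent
Type-I OLS decomposition). Variance-explained shares are SS_term/SS_total.
Treating all factors as random, the six components are solved from the
expected mean squares (method of moments) — closed-form, exactly unbiased
on balanced data — and negative solutions are truncated at zero, which
keeps h² in [0, 1]. REML would add a dependency and an iterative fit for
no benefit at these design sizes. Mildly unbalanced data are handled by
unweighted cell means with harmonic-mean replication and flagged
`unbalanced: MoM approximate`; empty cells are an error.

The h² divisors follow the equation this pipeline reproduces: σ²_G×C is
divided by the number of experiments n and σ²_G×E by the number of
conditions k. That placement looks swapped relative to the common
entry-mean convention (each interaction divided by the levels of the
non-genotype factor crossed with it), so a `divisor_convention`
switch (`"paper"` | `"conventional"`) exposes both; the default follows
the source equation.

The per-replicate h² estimate is a ratio of noisy components and is
Jensen-biased downward at realistic design sizes even though every
component estimate is unbiased; recovery is therefore judged by plugging
the *mean* component estimates into the h² formula, which is the
meaningful plug-in comparison.

Contrasts of each stress against control are the treatment-coded
condition coefficients of an additive OLS model with genotype and
experiment as blocking factors — the cell-balanced marginal mean
difference — tested two-sided with no multiplicity adjustment (declared
in the output; adjust downstream if many traits are screened).

## Synthetic-data generator

The generator emulates the statistical structure of a multi-experiment
glasshouse factorial: 8 genotypes × 6 post-flowering conditions × 4
experiments × 4 replicate plants by default. Anchors for the control
condition are the printed summary means of the emulated design: organ DW
230/1590/840 mg (rosette/stem/seeds), N allocation 7/53/40 %, ¹⁵N
allocation 9/40/51 %, seed N% 4.0 on the line C% = 70.7 − 4.0·N%. Stress
profiles move each quantity in the reported direction (e.g. heat: seed DW
multiplier 0.024, stem N allocation 95 %, ¹⁵N trapped in the stem; low N:
all organs shrunk, allocation shifted to seeds, steeper/lower line).

Mechanics, layer by layer:

- **Dry weights** are log-normal around condition-specific means (biomass
  is positive and right-skewed) with genotype, experiment and G×C effects
  on the log scale. Genotype DW effects are plant-size effects shared by
  all organs, so by default the genotype component of HI/NHI is nil — the
  generator targets the heritability structure of the *composition*
  traits, not of the biomass ratios.
- **Seed composition** is placed on the stratum's trade-off line at a
  genotype- and condition-dependent N% (with G×C, G×E, C×E, G×C×E and
  residual layers), then displaced orthogonally by a genotype-persistent
  ΔSC offset plus Gaussian noise. The genotype offsets along the line and
  the ΔSC offsets are deliberately uncorrelated: correlated along-line and
  orthogonal effects would rotate the population major axis away from the
  generating line. Each experiment jitters the line (SD 0.3 slope, 1.2
  intercept — the latent drift, smaller than published across-experiment
  SDs, which include estimation error).
- **Nitrogen pools** are driven by target allocation fractions: the seed
  pool follows from seed DW × N%, the plant total is back-computed from
  the seed target share, and the rest splits between rosette and stem. In
  the zero-noise limit (`SyntheticConfig.zero_noise()`) the mass-balance
  module recovers the configured fractions *exactly*, so those tests are
  sharp rather than statistical.
- **¹⁵N label**: a fixed excess-¹⁵N dose (default 0.05 mg/plant,
  the order of magnitude of a single 10 mM, 10 atom % pulse) is split by
  condition-specific remobilisation fractions and organ atom percents are
  back-computed, making the tracer bookkeeping exact by construction.
  Enrichment above a cap (default E% = 5) — reachable only for the
  near-empty N pools of sterile plants — is treated as unrecovered tracer
  so A% stays physical.
- **Heat / sterility**: heat plants have ~2 % of the control seed DW and a
  10 % per-plant probability of a fully sterile seed lot below the
  degenerate guard, exercising every downstream guard path.

Calibration of the noise layers places the simulated heritabilities in
the reported ordering for this family of experiments: h²(ΔSC) ≈ 0.99 ≫
h²(C%) ≈ 0.4–0.6, with h²(N%) higher than the published point estimate
but robustly below ΔSC. Condition-level C% means follow from the line
geometry once the slope/intercept shifts and N% shifts are fixed; where
published summaries of C% shifts and line shifts are mutually
inconsistent under a shared line, the generator honours the line-shift
and N%-shift directions. NUtE under heat is emergent from the
seed-driven N bookkeeping and comes out high rather than low; nothing
downstream depends on it.

What the generator does **not** model — and hence what passing tests do
not establish about real data: no mechanistic growth or C/N flux
physiology, no measurement-instrument error structure (IRMS drift,
weighing error), no correlation between organ sizes beyond the shared
plant-size effect, no missing-organ or harvest-failure patterns, and
genotype effects on biomass partitioning are off by default.

## Numerical choices and edge cases

- Allocation fractions use max(Qty¹⁵N, 0) in numerator and denominator;
  sums equal 1 to machine precision (asserted at 1e-9 in tests).
- The identities NUE·HI = NHI and NRE·HI = ¹⁵NHI hold to 1e-9 relative
  tolerance by construction and are property-tested.
- CSV round-trips: floats at 12 significant digits, integers exact, NaN
  as the empty field. Validation is collect-then-fail with row-addressed
  messages; rows are never silently dropped.
- Standard errors need n ≥ 2 and are reported as missing otherwise; empty
  summary cells are missing, not zero.
- Pipeline outputs are byte-deterministic for a given config and seed;
  wall-clock timestamps appear only in `run.log`.

## Problem sizes used in the shipped checks

The acceptance script and test suite run the default 8×6×4×4 design (768
plants) for dataset-level checks, 500 balanced replicates for
variance-component recovery, 100 simulated datasets for the heritability
ordering, 100 stratified permutations for the null, 500 null simulations
for contrast calibration, 200 random point sets against the TLS grid
oracle and 1,000 random pairs against the ΔSC projection oracle — sizes
at which the Monte-Carlo error of each summary is comfortably below the
tolerance being asserted.

## Known limitations

- Method-of-moments components are approximate under strong imbalance;
  the flag is informational, not a correction.
- The contrast model is additive (no genotype × condition interaction
  term); it estimates the average stress effect across genotypes.
- ΔSC against a stratum line estimated from few plants inherits that
  line's estimation error; with very small strata consider
  `mode="pooled"`.
- The h² divisor default follows the source equation; users comparing
  against textbook entry-mean heritabilities should use
  `divisor_convention="conventional"`.
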