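# Methods

This note documents the models implemented in `isopool`, the defaults and
the reasoning behind them, the numerical choices, and what the simulator
does and does not emulate.

## 1. Zero-order pool dilution

### Model

Each plant-available soil N pool (NH₄⁺ or NO₃⁻, µg N g⁻¹ dry soil) is
modelled over the labelling window with constant (zero-order) gross fluxes:
production `f` adds N at natural-abundance ¹⁵N (ammonification feeds the
NH₄⁺ pool from organic N; nitrification feeds the NO₃⁻ pool from — in the
relevant labelling arrangement — unlabelled NH₄⁺), and consumption `c`
removes N at the pool's current enrichment. Writing `a` for atom% excess
(abundance above the 0.3663 atom% air-N₂ background):

    M(τ) = m0 + (f − c)·τ
    a(τ) = a0 · (M(τ)/m0)^(−f/(f−c)),   a(τ) = a0·e^(−fτ/m0) when f = c.

Zero-order kinetics are the standard assumption for windows of 10–20 d;
they make the pool-size trajectory linear and the enrichment trajectory a
power law, both invertible from a two-point observation.

### Estimator

From the pool observation (m₀, a₀) at the first harvest and (m_t, a_t) at
the second, Δt days later:

    f = (m0 − mt)/Δt · ln(a0/at) / ln(m0/mt)     if mt ≠ m0
    f = m0/Δt · ln(a0/at)                        in the mt → m0 limit
    c = f − (mt − m0)/Δt

The constant-pool limit is taken when |m_t − m₀| ≤ 1e−9·m₀. Unlabelled or
completely diluted pools (a₀ ≤ 0 or a_t ≤ 0) raise an estimation error;
negative rates (e.g. enrichment rising between harvests) are returned with
a diagnostic flag and never clamped, because truncation at zero would bias
every downstream mean and regression.

Δt is always taken from `harvest_day` differences in the data (nominally
13 d for harvests 1 d and 14 d after labelling), never hard-coded, so the
pipeline is correct for any harvest schedule.

### Mean pool enrichment

Plant uptake needs the time-weighted mean excess of the source pool,
ā = (1/Δt)∫₀^Δt a(τ)dτ. With k = (f−c)/m₀ and p = f/(f−c) the closed form

    ā = a0·[(1 + kΔt)^(1−p) − 1] / (kΔt·(1−p))

is evaluated through the algebraically equivalent expression

    ā = a0 · expm1(−q·r) / (−q),   q = cΔt/m0,   r = log1p(kΔt)/(kΔt),

which is uniformly stable: it passes continuously through the balanced
limit f = c (where the naive form is 0/0), the no-consumption limit c = 0
(ā = a₀·ln(1+kΔt)/(kΔt), handled by a series branch at |q| < 1e−10), and
the no-production limit f = 0 (ā = a₀, recovered exactly by the same
expression). `r` switches to its Taylor series for |kΔt| < 1e−8. The
closed form is validated against adaptive quadrature of a(τ) (and against
direct numerical ODE integration in the acceptance checks) to better than
1e−8 across a parameter grid that brackets all the limits. A modelled pool
that is exhausted inside the window (1 + kΔt ≤ 0) raises an estimation
error rather than returning a complex power.

### Plant uptake

Uptake of *total* N (not just tracer) from the labelled pool between the
harvests is

    U = (E_t14 − E_t1) / (ā/100),    E = plant N content × atom% excess/100,

i.e. the between-harvest increment of plant ¹⁵N excess divided by the mean
source enrichment. Two readings of the uptake procedure were possible:
dividing the single-harvest plant excess at t₁₄, or the t₁₄ − t₁
increment. The increment is implemented as the default because the
destructive t₁/t₁₄ pairing exists precisely to difference out label
acquired during the 24 h mixing incubation before the first harvest; with
a per-pot uptake that is constant over the window the two readings differ
only by the label taken up in that first day. Similarly, ā is computed
over the between-harvest window [t₁, t₁₄] by default; a `from_labelling`
option extrapolates the fitted model back to the labelling time and
averages over [0, t₁₄] instead.

The per-capita daily rate divides U by Δt and by a biomass normaliser —
the plant's t₁ biomass by default (the pair's initial size is the natural
denominator for a rate measured from that baseline), with the geometric
mean of the two harvest biomasses as a configurable alternative. The
conventional reporting unit (mg N g⁻¹ d⁻¹) does not pin the denominator; both options
are exposed and the default is stated in every output table.

Pairs whose aboveground biomass did not increase between harvests are
excluded from uptake estimation — the procedure presumes net growth over
the window — and every exclusion is written to a ledger with its reason;
nothing is silently dropped.

## 2. Isotope bookkeeping

- **Backgrounds.** Default natural abundance is 0.3663 atom% (air N₂),
  overridable per dataset. Below-background excesses are flagged, not
  truncated.
- **Carrier correction.** Diffusion-trap samples with too little N for
  mass spectrometry receive unlabelled carrier N (default 40 µg). The
  measured excess is corrected by two-pool ¹⁵N mass balance:
  `excess = measured × (sample_n + carrier_n)/sample_n` for a carrier at
  background, with the carrier's own excess contribution subtracted in the
  general form. The forward mixing and the correction are exact inverses
  and linear in the measured excess.
- **Extract conversion.** KCl-extract concentrations (mg N l⁻¹) convert to
  µg N g⁻¹ dry soil by mass balance, counting the water carried in the
  moist soil as part of the solution volume.

## 3. Growth and climate

- **RGR** between paired harvests: (ln W₂ − ln W₁)/Δt, the classical mean
  relative growth rate. Negative values (shrinkage) are legitimate growth
  observations and are flagged.
- **GDD**: daily max(0, (T_max + T_min)/2 − 5.6 °C), the base temperature
  below which *Dactylis glomerata* does not grow, accumulated over a
  window counting positive days only. The max/min average is used as the
  daily mean (the usual convention when only extremes are logged).
  Calendar gaps are reported, never interpolated — no imputation rule is
  defensible without knowing the logger failure mode. Season-cumulative
  GDD totals require that season's daily station records, so the module
  is validated on synthetic series with hand-computed totals.

## 4. Competition ANCOVA

Each response of the competing *Dactylis* — per-ion per-capita uptake,
RGR, aboveground biomass — is paired with the same metric for the isolated
*Dactylis* from the same block, replicate, fertiliser level and label
(biomass additionally by harvest). The full model is

    response ~ covariate + location + fertiliser (+ harvest)
               + all two-way interactions,

fitted by OLS under treatment contrasts. Backward simplification removes
interaction terms only: at each step the interaction whose removal has the
largest nested-model F-comparison p-value is dropped if that p exceeds
alpha (default 0.05), iterating until every remaining interaction is
significant. Main effects are never removed. Ties in p are broken towards
the term latest in a fixed canonical order (covariate first, then factors,
then interactions in combination order), making the simplification trail
fully deterministic; numerically-zero sum-of-squares contributions (exact
fits) are treated as p = 1 so saturated noiseless fits simplify cleanly.

Residuals of the final model are checked with Shapiro–Wilk (normality) and
Breusch–Pagan (heteroscedasticity); the specific tests are this package's
choice, since only the checks themselves, not the statistics, are
conventionally reported. If either fails at alpha and all values are
positive, response and covariate are log-transformed and the model refitted
once; zeros suppress the transform with a note. Replicates within blocks
enter individually — the possible data-point counts (48 per ion, 96 for
RGR, 192 for biomass) only arise without pre-averaging. Block is never a
term in the main models; it is tested separately against each response and
reported.

The 1:1-line summary classifies each treatment cell by a two-sided paired
t-test of response − covariate at alpha: significantly negative means the
competing plant captures less than its isolated control (competition,
"below" the line of equality), significantly positive means facilitation
("above"), otherwise "on". Degenerate cells (all differences identical)
classify by the sign of the common difference.

Competition indices are deliberately not implemented; the paired-covariate
design is the statistically sound alternative.

## 5. The forward simulator

### What it emulates

The full two-site experiment: 6 blocks × 2 replicates of the
2 (fertiliser) × 2 (combination) × 2 (¹⁵N label) × 2 (harvest) cross at
each site — 192 pots per site, 12 per treatment cell — with harvests 1 d
and 14 d after labelling. Each pot receives 15 mg label N (half per
moiety, the labelled half at 99 atom%) into 3 kg dry soil; both soil pools
then follow exact zero-order kinetics. Consumption is a microbial sink
plus the plants' draw; each plant draws at a constant rate equal to its
specific uptake rate (mg N g⁻¹ d⁻¹) times its true t₁ biomass, so the
estimator's assumptions hold *exactly* and noiseless simulation plus
estimation recovers every generating parameter to numerical precision
(the basis of the round-trip tests; observed max relative error ~1e−14).

Soil parameter defaults are the study's per-treatment means: gross
ammonification 0.158–0.246 and nitrification 0.088–0.128 µg g⁻¹ d⁻¹, and
pre-label pool concentrations (NH₄⁺ 0.81–4.49, NO₃⁻ 0.003–0.040 µg g⁻¹ —
NO₃⁻ below 5% of NH₄⁺ in every treatment, and ammonification:nitrification
ratios spanning 1.3–2.8). Microbial NH₄⁺ consumption defaults to
nitrification plus half of ammonification (immobilisation); the NO₃⁻ sink
to 0.05 µg g⁻¹ d⁻¹ — values chosen once as ecologically plausible for a
sandy loam and checked only for pool positivity.

The uptake structure reproduces the qualitative competition pattern of the
study: specific NH₄⁺ uptake exceeds NO₃⁻ uptake (0.20 vs 0.12 mg N g⁻¹
d⁻¹ for isolated *Dactylis*), NH₄⁺ uptake rises 1.5× under high
fertiliser for every plant (a supply effect, not competition), isolated
NO₃⁻ uptake is fertiliser-independent, and the presence of *Plantago*
halves *Dactylis*' specific NO₃⁻ uptake under high fertiliser only, never
its NH₄⁺ uptake. Growth defaults make isolated plants larger but competing
plants faster-growing over the window, except under low fertiliser at the
upland site.

Measurement noise is multiplicative lognormal for concentrations (CV 0.10)
and plant N (CV 0.08), Gaussian for biomass (CV 0.10), and lognormal on
the ¹⁵N/¹⁴N isotope *ratio* for enrichments (CV 0.03) — ratio-scale noise
is what an isotope-ratio mass spectrometer delivers and keeps every
reported abundance inside the physical (0, 100) atom% range even for
nearly pure-label pools. The carrier dilution/correction chain is applied
(exactly) inside the measurement path. These CVs are assumptions: real
between-pot variance components are not available to calibrate against,
so the defaults represent instrument-scale noise and are labelled as such.
Pair loss — a t₁₄ plant failing the growth precondition — is imposed on a
configured fraction of pairs (default 0.10, giving exclusion counts of the
same order as the losses such paired designs typically incur).

A ground-truth ledger records every generating rate, mean enrichment,
uptake and RGR per design cell and species. A `null` scenario removes all
treatment, competition and growth contrasts for type-I studies.

### What it does not emulate

No mechanistic microbial or root-architecture dynamics; no cross-pool ¹⁵N
transfer (nitrification of labelled NH₄⁺ into the NO₃⁻ pool is routed to
the consumption sink — consistent with the estimator's assumption set, and
the labelling arrangement used for estimation never reads the unlabelled
pool's enrichment); no remineralisation of microbial ¹⁵N; no root
biomass, belowground N, light competition or phenology. Label enters the
pools instantaneously at τ = 0; the 24 h incubation exists only as the
t₁ = 1 d harvest offset. Isotope-excess linearity therefore holds in the
label's *enrichment* (doubling the label's atom% excess doubles every
excess), while the label's mass is part of the pool-size budget.
Consequently, passing tests demonstrate correctness of the estimation
machinery under its own assumptions and realistic noise — not robustness
to model misspecification in real soils, which the first-order-consumption
discussion below touches.

### Conservation

With noise off, total ¹⁵N excess (labelled pool + plants + microbial sink)
is conserved to better than 1e−9 relative at all times in every design
cell, computed from the same closed-form integrals the estimator uses.

## 6. Problem sizes and runtimes

The test suite and acceptance script size their Monte-Carlo components as:
a ≥100-point (f, c, m₀, a₀) grid for estimator round trips against an
independent ODE oracle; 1000 null replicates (3000 term decisions) for the
interaction-retention type-I check, asserted within 3 binomial σ of
alpha = 0.05; 40 replicates of the full design at CV = 0.05 for the noisy
rate-recovery check (median |relative error| of f < 15%); and 100 seeded
replicates of the default scenario for the competition-pattern check,
asserted per treatment cell at ≥90% agreement. The whole suite runs in
about two minutes; the acceptance script in about one.

## 7. Known limitations

- Gross-rate estimation assumes the zero-order model; first-order or mixed
  kinetics bias the estimates (the simulator's architecture would admit a
  first-order consumption option for such robustness studies, which is
  out of scope here).
- Aboveground measurements only: root N capture is invisible, as in the
  original design.
- The ANCOVA treats pots as independent given block pairing; no
  mixed-effects alternative is provided (deliberately: the paired-covariate
  fixed-effects model is the analysis this pipeline implements).
- Diagnostics-triggered log transformation is all-or-nothing per response;
  no Box-Cox search.
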