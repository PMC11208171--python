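# Methods

## The electron-flow model

The model is a deliberately small stoichiometric network — about fifteen
reactions — describing acetogenesis in *Acetobacterium woodii* at the
level of its redox-carrier ledger. Species carry two conserved quantities:
carbon atoms and a degree of reduction (electrons relative to the fully
oxidized reference states CO₂, NAD⁺, oxidized ferredoxin and free THF;
each two-electron reduction step adds 2). Every non-exchange reaction must
balance both exactly, which is asserted in rational arithmetic with no
tolerance.

Assumptions inherited from the underlying bioenergetic scheme:

- **Chemiosmotic coupling.** Rnf pumps 2 Na⁺ per Fd²⁻ oxidized (1 Na⁺ per
  electron); the ATP synthase consumes 33/10 Na⁺ per ATP, reflecting its
  c-ring gear ratio. Both are `ModelParameters` and can be varied, but the
  defaults define the canonical scenarios.
- **ATP is a ledger, not a balanced species.** Substrate-level
  phosphorylation (acetate kinase +1, formyl-THF synthetase −1, lumped
  fructose catabolism +4) is summed as `slp_net`; chemiosmotic ATP is
  realized as ATP-synthase flux because the translocated-Na⁺ pool *is*
  balanced, which forces synthase flux = Na⁺ pumped / (Na⁺/ATP).
- **The methyl branch is lumped** into two NADH-consuming steps
  (formyl-THF → methylene-THF including the cyclohydrolase, and
  methylene → methyl-THF); the ledger does not resolve finer THF
  chemistry, because no carrier other than NADH enters or leaves there.
- **HydABC flux unit**: one unit oxidizes 2 H₂ and produces 1 Fd²⁻ +
  1 NADH (the four-electron bifurcation event), reversible. This keeps all
  canonical fluxes small rationals.
- **Fructose catabolism is one lumped reaction**
  (fructose → 2 acetate + 2 CO₂ + 2 NADH + 2 Fd²⁻ + 4 ATP), since only its
  carrier and acetate output matter to the ledger.
- **Carbonyl-branch entry is exclusive**: when CO is available the
  acetyl-CoA synthase receives CO directly; otherwise the CODH of the
  CODH/ACS complex reduces CO₂ at the cost of one Fd²⁻. Including both
  routes alongside CooS would create a futile cycle (CooS + CODH-carbonyl
  is stoichiometrically identical to direct entry) — an unobservable free
  direction, which the solver would rightly refuse.
- **Genotype/condition gating removes reactions** rather than bounding
  them at zero: Na⁺ depletion removes Rnf and the ATP synthase,
  bicarbonate uncoupling (ATP depletion) removes the ATP-dependent
  formyl-THF synthetase, and the hydrogenase-free genotype removes HydABC
  and the H₂-mode HDCR. Infeasibility diagnostics then name the species
  that cannot balance instead of reporting an opaque bound.
- **Wild-type ferredoxin-mode HDCR is off by default.** The purified
  enzyme shows ~6 % of its H₂-mode rate with Fd²⁻, which the canonical
  wild-type ledgers ignore; a genotype flag allows turning it on for
  exploration.
- **H₂ escape.** The wild type on formate cycles H₂ through the headspace
  and some may be lost; the default ledger is closed
  (`h2_escape_fraction = 0`). A nonzero fraction *f* adds the constraint
  that exported H₂ equals *f* × (HDCR-produced H₂). Losing H₂ raises the
  formate:acetate ratio (3/(1−f) + 1 : 1) but leaves the Rnf ledger and
  hence the ATP yield per acetate unchanged — the lost electrons are made
  up by extra formate oxidation, not by shorting Rnf.

## The solver

The network is solved per unit product, not optimized. The balance matrix
over all internal species (everything except the ATP ledger) is stacked
with the product-normalization row(s) and solved by exact Gauss–Jordan
elimination over rationals (sympy). Three outcomes are possible:

1. **Unique solution**: returned with per-carrier ledgers, the Na⁺ ledger
   and the ATP yield, all exact. Irreversibility is checked *post hoc*: a
   negative flux through an irreversible reaction converts the result into
   an infeasibility report carrying the signed fluxes, because the unique
   mathematical solution is not chemically realizable.
2. **Under-determined**: a residual null space (beyond the φ product
   split, which the target fixes) raises an error listing the reactions of
   each free direction. This is treated as a modeling bug, never resolved
   silently.
3. **Infeasible**: inconsistency is certified by a left-null-space vector
   y with y·b ≠ 0 — a linear combination of species balances that
   contradicts the requested product flux. The species in the support of
   the smallest such basis vector are reported as the unbalanceable set
   (support minimality is heuristic — the smallest *basis* vector is
   chosen, not the global minimum — but the certificate itself is exact).

The mixed-product resting-cell scenario exposes φ, the formate fraction of
total product flux; solutions are linear in φ, interpolating between the
pure-acetate and pure-formate ledgers. The default φ = 1/2 mirrors the
observed roughly equimolar acetate/formate endpoints and yields
CO:acetate:formate = 5:1:1; the observed 5.3:1:1 is within measurement
rounding of that, and no mechanism for the split is claimed.

## Analysis operations

- **Ratios and fold changes** are simple quotients with half-up rounding
  at the printed precision (1 decimal; fold changes ≥ 10 are reported as
  integers, matching convention). Raw values are floats computed from the
  caller's measurements; rounding happens only at the boundary.
- **Growth rate** is the slope of ln(OD) versus time over a contiguous
  window of at least 4 points. Windows are scored by R²; because R²
  differences below 0.01 carry no evidence about which window is "more
  exponential", scores are compared at two decimals and near-ties resolve
  to the longer, then the earlier window. A noiseless exponential is thus
  fitted over the whole series (exact recovery), and under 5 % noise the
  selection cannot be won by a lucky 4-point window. Flat series are
  reported as degenerate (μ = 0, R² undefined) rather than an error.
- **Specific rates** convert mM/h in a fixed-volume suspension to
  nmol min⁻¹ mg⁻¹ via ×1000/60 and the protein concentration (mg/mL),
  the implicit convention of resting-cell assays.
- **SNP reports** filter a variant table by population frequency at one
  timepoint and sort by descending frequency then ascending position (a
  total order). Blank cells mean "variant not detected" and are treated
  as 0 % with a provenance flag. The packaged table
  (`data/co_adaptation_snps.tsv`) is a transcription of the CO-adaptation
  variant frequencies; rows whose source text did not unambiguously
  assign a frequency to a timepoint column were placed conservatively
  (two-value rows at the later two timepoints, single minor variants at
  the final one) — none of these placements approaches the 75 %/100 %
  thresholds any analysis here uses.

## Synthetic data

The generators exist so every analysis operation and the flux model's
ratio predictions can be exercised end to end with known ground truth.

- **Growth curves** are logistic with a lag implemented as a time shift:
  OD(t) = K·od0 / (od0 + (K − od0)·e^(−μ(t−lag))). Defaults (od0 = 0.05,
  K = 1.0, μ = 0.05 h⁻¹, 0–168 h sampled every 3 h) emulate the adapted
  mutant's batch cultures on CO. Note that with K = 1.0 the *true*
  ln-slope never exceeds μ(1 − od0/K); recovering μ itself to better than
  that correction requires sampling a culture far from saturation, which
  is what the parameter-recovery tests do (K ≫ observed OD range,
  horizon ending pre-saturation) — exactly how μ is measured at the
  bench.
- **Conversion time courses** consume the substrate linearly at a
  configured specific rate until exhaustion; each product of the supplied
  flux solution rises in its exact stoichiometric proportion, including
  the gaseous products (CO₂, H₂) so that carbon is conserved point by
  point along noiseless trajectories. Liquid-phase analyses simply ignore
  the gas series.
- **Noise** is multiplicative lognormal with unit mean (concentrations
  and ODs are positive), CV 5 % by default. All randomness flows through
  an explicit `numpy.random.default_rng(seed)`; equal seeds give
  bit-identical output.
- **SNP tables** draw one locus sweeping monotonically to 100 % at the
  final timepoint and the rest fluctuating below 90 %.

What passing these tests does *not* show: the generators are phenomenological
(no Monod/ODE kinetics, no CO toxicity or inhibition, no gas–liquid
transfer, no six-month adaptation lag, no replicate error structure), so
agreement on synthetic data validates the arithmetic and the fitting
procedure, not the biology of any particular culture.

## Numerical conventions

- All stoichiometry, fluxes, ledgers and yields are `fractions.Fraction`;
  floats appear only in measured-data operations and at reporting.
- Reporting rounds half-up (away from zero) at 1 decimal for yields and
  ratios, nearest integer for percent changes — matching printed
  laboratory precision. Exact values are always retained alongside.
- Models serialize to versioned JSON with rationals as `"p/q"` strings;
  genotype/condition presets and the scenario registry are YAML shipped
  with the package.

## Known limitations

- No thermodynamics (ΔG, redox potentials), no enzyme kinetics, no CO
  inhibition constants, no growth-yield (biomass per ATP) model: the
  doubling of biomass on formate is *consistent with* the 4× ATP yield but
  not derivable from this model.
- The wild-type-on-CO scheme is solvable stoichiometrically even though
  the wild type does not grow on CO; feasibility here means the ledger
  closes, not viability.
- Scenario problem sizes are those of the schemes themselves (12–14
  reactions); the solver is exact and not intended for genome-scale
  networks.
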