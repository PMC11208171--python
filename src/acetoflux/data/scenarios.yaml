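# Named scenarios: one per bioenergetic scheme or resting-cell condition.
# target.flux and target.phi are exact rationals serialized as "p/q".
schema_version: 1

scenarios:
  wt_h2co2:
    genotype: wild_type
    condition: h2_co2
    target: {product: acetate, flux: "1"}
    notes: >
      Wild type on H2 + CO2: HydABC bifurcation feeds Fd and NAD+, the
      H2-dependent HDCR reduces CO2 to formate. Expected net yield 0.3 ATP
      per acetate (10/33).
  wt_co:
    genotype: wild_type
    condition: co
    target: {product: acetate, flux: "1"}
    notes: >
      Wild type scheme on CO (stoichiometric solvability only; the wild
      type does not actually grow on CO, and CO toxicity is not modeled).
      CooS oxidizes CO to Fd2-; the methyl branch runs via reverse HydABC
      and the H2-mode HDCR. Expected 1.5 ATP per acetate (50/33).
  wt_formate:
    genotype: wild_type
    condition: formate
    target: {product: acetate, flux: "1"}
    notes: >
      Wild type on formate: three quarters of the formate taken up are
      oxidized to H2 + CO2 by the HDCR, H2 is recaptured by HydABC; only
      0.5 Fd2- per acetate reaches Rnf. Expected 0.3 ATP per acetate.
  mut_co:
    genotype: hydrogenase_free
    condition: co
    target: {product: acetate, flux: "1"}
    notes: >
      Hydrogenase-free mutant on CO: ferredoxin-mode HDCR replaces the
      H2 loop; 2 Fd2- per acetate reach Rnf. Expected 1.2 ATP per acetate
      (40/33), CO:acetate 4:1.
  mut_formate:
    genotype: hydrogenase_free
    condition: formate
    target: {product: acetate, flux: "1"}
    notes: >
      Hydrogenase-free mutant on formate: formate oxidation reduces Fd
      directly; all Fd2- is oxidized by Rnf. Expected 1.2 ATP per acetate,
      formate:acetate 4:1.
  mut_h2co2:
    genotype: hydrogenase_free
    condition: h2_co2
    target: {product: acetate, flux: "1"}
    notes: >
      Hydrogenase-free mutant on H2 + CO2: no H2-oxidizing reaction exists,
      so the scenario is infeasible (the strain does not grow).
  mut_fructose:
    genotype: hydrogenase_free
    condition: fructose
    target: {product: acetate, flux: "1"}
    notes: >
      Hydrogenase-free mutant on fructose: glycolytic NADH/Fd2- exactly
      cover the reductive branch via ferredoxin-mode HDCR (homoacetogenesis,
      fructose:acetate 1:3 stoichiometric ideal).
  resting_na_depleted_co:
    genotype: hydrogenase_free
    condition: co_na_depleted
    target: {product: formate, flux: "1"}
    notes: >
      Resting cells, Na+ depleted: without Rnf/ATP synthase NADH cannot be
      regenerated, acetogenesis stops, and CO is converted to formate only
      (CO:formate 1:1).
  resting_uncoupled_co:
    genotype: hydrogenase_free
    condition: co_uncoupled
    target: {product: formate, flux: "1"}
    notes: >
      Resting cells, 300 mM bicarbonate: ATP depletion blocks the
      formyl-THF synthetase, so CO goes to formate only (CO:formate 1:1).
  resting_mixed_co:
    genotype: hydrogenase_free
    condition: co
    target: {product: acetate, flux: "1", phi: "1/2"}
    notes: >
      Resting cells with 60 mM bicarbonate produce acetate and formate
      side by side; modeled as a phi-split between the acetate-producing
      and formate-producing modes (default phi = 1/2, i.e. ~1:1 products,
      giving CO:acetate:formate 5:1:1).
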