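# Genotype and condition presets addressable by name.
schema_version: 1

genotypes:
  wild_type:
    hydABC_present: true
    hdcr_hydrogenase_module_present: true
    hdcr_fdh_module_present: true
    fd_hdcr_enabled: false
    cooS_present: true
    rnf_present: true
    label: "wild type (both [FeFe] hydrogenases present)"
  hydrogenase_free:
    hydABC_present: false
    hdcr_hydrogenase_module_present: false
    hdcr_fdh_module_present: true
    fd_hdcr_enabled: true
    cooS_present: true
    rnf_present: true
    label: "CO-adapted hydrogenase-free mutant (ferredoxin-mode HDCR)"

conditions:
  h2_co2:
    substrates_available: [h2, co2]
    na_available: true
    atp_coupling_available: true
    co2_available_as_acceptor: true
  co:
    substrates_available: [co]
    na_available: true
    atp_coupling_available: true
    co2_available_as_acceptor: true
  formate:
    substrates_available: [formate]
    na_available: true
    atp_coupling_available: true
    co2_available_as_acceptor: true
  fructose:
    substrates_available: [fructose]
    na_available: true
    atp_coupling_available: true
    co2_available_as_acceptor: true
  co_na_depleted:
    substrates_available: [co]
    na_available: false
    atp_coupling_available: true
    co2_available_as_acceptor: true
  co_uncoupled:
    # high bicarbonate depletes ATP; the ATP-dependent formyl-THF
    # synthetase cannot run
    substrates_available: [co]
    na_available: true
    atp_coupling_available: false
    co2_available_as_acceptor: true
  co_no_bicarbonate:
    substrates_available: [co]
    na_available: true
    atp_coupling_available: true
    co2_available_as_acceptor: false
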