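# RAS/PI3K activation constants and the (drug x EGFR mutation) inhibition table.
# Rates in L/mol/s (activation) and 1/s (deactivation); pools in mol/L.
# ki_nM and ki_over_km_atp are the published inhibition constants and
# Ki/Km_ATP ratios; km_atp per mutation is back-derived from the
# mutually consistent osimertinib rows (see docs/methods.md).
activation:
  ka_ras_by_met: 1.89e+6
  ka_ras_by_vegfr: 1.34e+3
  ka_ras_by_egfr: 1.89e+6
  kda_ras: 1.0
  ka_pi3k_by_met: 4.69e+6
  ka_pi3k_by_vegfr: 9.99e+7
  ka_pi3k_by_egfr: 6.04e+5
  ka_pi3k_by_ras: 3.94e+4
  kda_pi3k: 1.0
pools:
  ras_total: 1.0e-5
  pi3k_total: 1.0e-5
inhibition:
  formula_variant: standard
  ki_nM:
    gefitinib:
      ex19del+t790m: 43.0
      ex21ins+t790m: 29.0
      ex19del: 83.0
      ex20_sensitive: 2.5
      ex20_resistant: 26.0
      ex21ins: 6.4
      wild_type: 16.0
    osimertinib:
      ex19del+t790m: 0.032
      ex21ins+t790m: 0.0094
      ex19del: 1.1
      ex20_sensitive: 0.59
      ex20_resistant: 6.2
      ex21ins: 0.97
      wild_type: 3.3
  ki_over_km_atp:
    gefitinib:
      ex19del+t790m: 5.1e-3
      ex21ins+t790m: 3.4e-3
      ex19del: 6.5e-6
      ex20_sensitive: 1.3e-4
      ex20_resistant: 7.0e-4
      ex21ins: 4.3e-5
      wild_type: 3.2e-3
    osimertinib:
      ex19del+t790m: 3.8e-6
      ex21ins+t790m: 1.1e-6
      ex19del: 8.5e-6
      ex20_sensitive: 3.1e-5
      ex20_resistant: 1.7e-4
      ex21ins: 6.5e-6
      wild_type: 6.4e-4
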