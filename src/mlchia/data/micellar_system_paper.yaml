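# Physiological bile-salt / lecithin mixed micellar mobile phase:
# six bile salts in intestinal molar ratios plus egg phosphatidylcholine,
# in 10 mM HEPES pH 6.5 with 0.15 M NaCl.  Component CMCs are literature
# values for the pure bile salts in 0.15 M NaCl.
components:
  - {name: NaTC,  conc_mM: 2.71, cmc_M: 0.004}
  - {name: NaTDC, conc_mM: 2.00, cmc_M: 0.0024}
  - {name: NaDC,  conc_mM: 2.08, cmc_M: 0.0024}
  - {name: NaC,   conc_mM: 2.08, cmc_M: 0.0075}
  - {name: NaGC,  conc_mM: 4.70, cmc_M: 0.009}
  - {name: NaGDC, conc_mM: 3.43, cmc_M: 0.0022}
lecithin_mM: 0.75
nacl_M: 0.15
ph: 6.5
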