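# Demo scenario: synthetic two-genotype census at the field study's scale
# (~1600 monitored plants, 4 annual transitions, 40 blocks, negatively
# correlated drought and herbivory), then the full fitting / surface /
# bootstrap / classification pipeline at reduced bootstrap settings.
output_dir: results/demo
synthetic:
  seed: 11
  n_plants: 800          # per genotype
  n_years: 4
  n_blocks: 40
  moisture_range: [4.0, 20.0]
  herbivory_dispersion: 8.0
  moisture_herbivory_corr: -0.4
grid:
  n_bins: 25
  herbivory_floor: 0.5
mesh:
  m: 60                  # library default is 100; reduced for the demo
bootstrap:
  B: 200                 # library default is 1000; reduced for the demo
  seed: 12
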