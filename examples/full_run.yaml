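# End-to-end example configuration: simulate a duplex library with all four
# error classes plus a low-level true mutation load, then process it.
mode: full
seed: 7
output_dir: run
simulation:
  n_fragments: 5000
  family_size_distribution: [poisson_shifted, 6.0]
  true_mutation_frequency: 1.0e-5
  sequencing_error_rate: 1.0e-3
  damage_error_rate: 1.0e-4
  late_pcr_error_rate: 1.0e-4
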