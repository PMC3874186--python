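# Full configuration schema for ribotraffic (every key optional; the values
# shown are the package defaults unless commented otherwise).

locus:
  gene_length: 6900          # bp, 35S transcription unit
  n_copies: 150
  first_cpd_region_length: 2960
  short_fragment_length: 860
  spacer_length: 2440        # intergenic spacer (negative coordinates)
  # amplicon_midpoints:      # replaces the default qPCR panel outright
  #   a: -1200
  #   c: 800
  # tro_fragments:
  #   2: [700, 1650]
  #   3: [2900, 3850]
  #   4: [5700, 6650]
  # regions:
  #   18S: [0, 2230]
  #   25S: [3800, 6700]

damage:
  # default: piecewise profile calibrated from the two measured damaged
  # fractions (0.554/kb over the first 860 bp, ~0.756/kb beyond).
  # uniform_rate_per_kb: 0.7          # switch to a uniform profile
  # segments:                         # or give the profile explicitly
  #   - {start: 0, end: 860, rate_per_kb: 0.554}
  #   - {start: 860, end: 6900, rate_per_kb: 0.756}

kinetics:
  k_tcr: 1.3863              # per h (half-life 30 min)
  k_ggr: 0.3466              # per h (half-life 2 h)
  tcr_rule: arrest           # or open_copy
  pp64_repair_multiplier: 1.0

dynamics:
  elongation_rate: 25        # nt/s
  steady_spacing: 130        # bp between polymerases on an active copy
  footprint: 65              # bp exclusion
  release_mode: both         # collision | constant | both
  k_release: 0.05            # per min, spontaneous release when arrested
  k_collision: 4.0           # per min while a trailing polymerase presses
  post_uv_initiation_factor: 1.0
  dt: 1                      # s

chromatin:
  deposition_delay: 5        # min of vacancy before nucleosomes load
  deposition_bin: 200        # bp
  open_threshold: 0.2
  closed_threshold: 0.8

assays:
  chip_background: 0.05

scenario:
  strain: WT                 # WT | rad14d (rad14d switches NER off)
  open_fraction: 0.5
  timepoints_h: [-0.25, 0.0, 0.5, 1.0, 2.0, 4.0]
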