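# Brushtail possum (Trichosurus vulpecula) defaults: half-normal detection
# parameters from the possum trapping literature, grid spacings per New
# Zealand best-practice possum control guidelines.
species: possum
detection:
  g0: 0.05
  sigma: 63.0          # metres; 2.45*sigma ~ 154 m (95% activity radius)
layout:
  trap_spacing: 50.0
  line_spacing: 100.0
  traps_per_line: 81
  n_lines: 26          # 2106 trap sites
  buffer: 100.0
  buffered_area: 1140.0   # hectares, including buffer
trapped_area: 1007.0      # hectares, excluding buffer (for per-ha costing)
density_range: [0.5, 3.0] # animals/ha, typical maintenance densities
immigration: null
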