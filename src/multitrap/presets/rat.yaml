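# Ship rat (Rattus rattus) defaults: small home ranges (sigma 32 m) force a
# dense 25 x 100 m grid; the simulated block is ~500 ha to keep the high
# densities (up to 11/ha) tractable.  Rats are the only species for which a
# reinvasion (immigration) process is modelled: a population equal to the
# initial one arrives spread evenly over the trapping period, weighted
# toward the perimeter.
species: rat
detection:
  g0: 0.03
  sigma: 32.0          # metres; 2.45*sigma ~ 78 m
layout:
  trap_spacing: 25.0
  line_spacing: 100.0
  traps_per_line: 140
  n_lines: 30          # 4200 trap sites
  buffer: 100.0
  buffered_area: 1148.0
trapped_area: 1014.0
density_range: [1.0, 11.0]
# Enable by passing `immigration: default` (or a full block) in a scenario;
# daily arrivals = initial density / 30.
immigration:
  total: null          # null -> equal to the initial resident population
  zone_weights: [0.6, 0.3, 0.1]   # outer, middle, inner
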