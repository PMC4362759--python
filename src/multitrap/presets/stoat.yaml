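# Stoat (Mustela erminea) defaults: stoats range widely (sigma 641 m), so
# traps are sparse -- 84 sites cover ~1000 ha.
species: stoat
detection:
  g0: 0.045
  sigma: 641.0         # metres; 2.45*sigma ~ 1570 m
layout:
  trap_spacing: 200.0
  line_spacing: 800.0
  traps_per_line: 12
  n_lines: 7           # 84 trap sites
  buffer: 300.0
  buffered_area: 1472.0
trapped_area: 1040.0
density_range: [0.02, 0.12]
immigration: null
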