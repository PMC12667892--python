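# Canonical single-target / single-obstacle reaching scene:
# start (0,0), target (30,30), obstacle at (15,15) with a 4-unit physical
# diameter and an 8-unit tolerance boundary.
scene:
  start: [0.0, 0.0]
  goals:
    - position: [30.0, 30.0]
  obstacles:
    - position: [15.0, 15.0]
      d_inner: 4.0
      d_outer: 8.0
  alpha: 0.1
  lam: 1.0
plant:
  dt: 0.01
  damping: 0.1
  sdn_scale: 0.2
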