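# Canonical white-adipocyte parameter set: a 40 um cell whose lipid droplet
# confines current flow to a 0.5 um shell, patched with a 2 um pipette.
c_m: 1 uF/cm^2
r_m: 100 kOhm.cm^2
r_i: 100 Ohm.cm
rho: 40 um
d: 0.5 um
pipette_diameter: 2 um
mode: current_clamp
stimulus:
  kind: step
  amplitude: 100 pA
  site: pipette_cap
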