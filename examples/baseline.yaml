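# Baseline shared-ventilation operating point: standard ventilator
# settings (18 breaths/min, 1 s inspiration, PEEP 5, P_max 32 cmH2O),
# bench-characterised circuit losses, two identical moderate-ARDS
# patients. Pinch valves pre-set so each patient receives a 15 cmH2O
# exhalatory driving pressure (see `dualvent` docs; K values come from
# tune_pinch_valves on this same configuration).
ventilator:
  BR: 18          # breaths/min
  t_ins: 1.0      # s
  PEEP: 5.0       # cmH2O
  P_max: 32.0     # cmH2O
  R_V: 1.5        # cmH2O/(L/s), exhalation-valve resistance

circuit:
  K_oneway: {value: 9.01e-4, unit: "cmH2O/(L/min)^2"}
  K_filter: {value: 4.80e-4, unit: "cmH2O/(L/min)^2"}
  K_PEEP:   {value: 1.24e-3, unit: "cmH2O/(L/min)^2"}
  K_pinch1: {value: 49.3, unit: "cmH2O/(L/s)^2"}
  K_pinch2: {value: 49.3, unit: "cmH2O/(L/s)^2"}
  peep_thresh: 0.0   # cmH2O added to patient 2's PEEP

patients:
  - {R: 5, C: 35, PEEP: 5, DP: 15}   # R in cmH2O/(L/s), C in mL/cmH2O
  - {R: 5, C: 35, PEEP: 5, DP: 15}

solver:
  rtol: 1.0e-3
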