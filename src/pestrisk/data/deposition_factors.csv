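# pestrisk reference table v1: deposition factors (ppm of applied mix; 0.1 mL/hL or mg/kg)
# tractor_closed_charcoal = tractor_closed_forced (0.1 ppm) reduced by the
# charcoal filter's 99%: 0.1 x (1 - 0.99) = 0.001 ppm.
equipment,ppm
knapsack,1000
towed_pipe_manual,100
tractor_open,10
tractor_closed_natural,1
tractor_closed_forced,0.1
tractor_closed_charcoal,0.001
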