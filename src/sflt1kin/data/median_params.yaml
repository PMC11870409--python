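# Reference baseline: component-wise median of the accepted multistart fits
# of the delayed (maturation) model to the three sFLT1 secretion time-course
# datasets.  Units: alpha #/cell/h; beta, gamma, delta 1/h; tau h.
model_id: M2
alpha: 1.419e5
beta: 5.123e-2
gamma: 1.215e-1
delta: 5.743e-2
tau: 1.958
epsilon: 0.0
kappa: 0.0
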