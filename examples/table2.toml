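# Standard microscale parameter set (Model 1, 1% branching probability,
# tip-to-tip anastomosis probability 0.2).  Maps to D = 1e-3, chi = 0.4,
# mu = 160, lambda = 1.6, t_IC = 0.2.
R = 200
P_m = 1.0
k = 100.0
tau = 0.00625
P_p = 0.01
a_n = 0.2
mode = 1
K_IC = 32
K_max = 320
seed = 0
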