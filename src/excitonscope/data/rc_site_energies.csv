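pigment,qmmm_w030,qmmm_w126,qm_w030,qm_w126,shift_w030,shift_w126
P_L,1.912,2.024,1.877,2.011,0.035,0.013
P_M,1.833,2.000,1.838,2.011,-0.005,-0.011
B_L,1.869,2.019,1.861,2.016,0.008,0.003
B_M,1.826,1.995,1.849,2.014,-0.023,-0.019
H_L,2.035,2.066,1.956,2.050,0.079,0.016
H_M,1.900,2.029,1.885,2.025,0.015,0.004
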