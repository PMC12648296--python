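pair,snapshot,state_index,energy_eV,f,nto_weight,hole_fragment,particle_fragment
P_L/B_L,50ns,1,1.992,0.27,0.72,P_L,P_L
P_L/B_L,50ns,,2.277,0.01,0.94,P_L,B_L
P_L/B_L,100ns,1,1.983,0.00,1.0,P_L,B_L
P_L/B_L,150ns,1,1.986,0.27,0.72,P_L,P_L
P_L/B_L,150ns,,2.289,0.00,1.0,P_L,B_L
P_L/B_L,200ns,1,2.000,0.13,0.45,P_L,P_L
P_L/B_L,200ns,1,2.000,0.13,0.38,B_L,B_L
P_L/B_L,200ns,,2.237,0.00,1.0,P_L,B_L
P_M/P_L,50ns,1,1.816,0.73,0.91,P_M/P_L,P_M/P_L
P_M/P_L,100ns,1,1.775,0.59,0.93,P_M/P_L,P_M/P_L
P_M/P_L,100ns,,2.707,0.00,0.95,P_M,P_L
P_M/P_L,150ns,1,1.863,0.62,0.91,P_M/P_L,P_M/P_L
P_M/P_L,150ns,,2.512,0.00,0.96,P_L,P_M
P_M/P_L,200ns,1,1.829,0.62,0.93,P_M/P_L,P_M/P_L
P_M/P_L,200ns,,2.713,0.00,0.97,P_L,P_M
P_M/B_M,50ns,1,1.992,0.15,0.56,P_M,P_M
P_M/B_M,50ns,1,1.992,0.15,0.28,B_M,B_M
P_M/B_M,50ns,,2.252,0.00,1.0,P_M,B_M
P_M/B_M,100ns,1,1.980,0.14,0.50,P_M,P_M
P_M/B_M,100ns,1,1.980,0.14,0.34,B_M,B_M
P_M/B_M,100ns,,2.175,0.00,1.0,B_M,P_M
P_M/B_M,150ns,1,1.992,0.18,0.48,P_M,P_M
P_M/B_M,150ns,1,1.992,0.18,0.36,B_M,B_M
P_M/B_M,150ns,,2.187,0.00,1.0,P_M,B_M
P_M/B_M,200ns,1,1.994,0.18,0.59,P_M,P_M
P_M/B_M,200ns,1,1.994,0.18,0.25,B_M,B_M
P_M/B_M,200ns,,2.471,0.00,1.0,B_M,P_M
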