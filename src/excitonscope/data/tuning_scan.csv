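species,omega,eps_homo,ip,eps_lumo,ea
BChl,0.30,-6.44,5.89,-1.97,2.42
BPh,0.30,-6.52,5.97,-1.85,2.32
BChl,0.126,-5.80,5.81,-1.94,1.89
BPh,0.126,-5.86,5.88,-1.83,1.81
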