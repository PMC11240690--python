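# synthetic three-line test spectrum (non-physical); electrons per decay
energy_ev,yield
100,3.0
500,2.0
2000,0.5
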