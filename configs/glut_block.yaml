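# Glutamate-transporter block experiment near the synapse (small store,
# strong exchanger). Run once as-is (control) and once with --block-glut.
stim: poisson
rate: 10.0
duration: 10.0
seed: 0
svr: 1.0
ratio_er: 0.03
I_NCX_max: 0.5
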