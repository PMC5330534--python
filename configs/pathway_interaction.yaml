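# Both pathways with a strong Na+/Ca2+ exchanger: oscillation suppression
# and Ca2+ export into the extracellular space.
stim: poisson
rate: 100.0
duration: 200.0
seed: 0
svr: 1.0
ratio_er: 0.15
I_NCX_max: 1.0
save_every: 20
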