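# Store-release pathway in isolation: Poisson-driven Ca2+ oscillations as a
# function of the ER volume fraction. Run with:
#   astrosim simulate --config configs/oscillation_onset.yaml --mglur-only -o onset.csv
stim: poisson
rate: 100.0
duration: 200.0
seed: 0
svr: 1.0
ratio_er: 0.15
mglur_only: true
save_every: 20
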