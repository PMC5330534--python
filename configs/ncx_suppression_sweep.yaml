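# Sweep spec (astrosim sweep --spec ... -o out/): oscillation summary over
# the store-size x exchanger-strength grid.
axes:
  ratio_er: [0.0, 0.05, 0.10, 0.15]
  I_NCX_max: [0.0, 0.0001, 0.001, 0.01, 0.1, 1.0]
seeds: [0, 1, 2]
stim: poisson
rate: 100.0
duration: 200.0
metric: oscillations
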