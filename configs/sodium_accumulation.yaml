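# Transmembrane pathway: intracellular Na+ loading under constant
# extracellular glutamate (transporter vs Na+/K+-ATPase balance).
stim: constant
glutamate: 100.0
duration: 200.0
svr: 1.0
ratio_er: 0.15
I_NCX_max: 0.0
save_every: 10
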