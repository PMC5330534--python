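# Response to a single action potential (spike time read from spike.txt,
# one time in seconds per line).
stim: spike_list
spike_file: configs/spike.txt
duration: 20.0
svr: 1.0
ratio_er: 0.06
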