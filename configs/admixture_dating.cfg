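# Admixture-time estimates across the four crossover models
kind = admixture
T_values = 2, 3, 4, 6
models = ss+intf, ss+poiss, sa+intf, sa+poiss
n_replicates = 15000
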