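# IBD-sharing variance across the four crossover models
# (full sibs through second cousins; quote SD and quartiles per cell)
kind = relatives
relationships = full-sibs, first-cousins, second-cousins
models = ss+intf, ss+poiss, sa+intf, sa+poiss
n_pairs = 10000
genome = human-scale
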