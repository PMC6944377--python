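# Rates of sharing at least one IBD segment in distant cousins, including
# all-female and all-male connecting lineages
kind = relatives
relationships = third-cousins, fourth-cousins, fifth-cousins, sixth-cousins, female-sixth-cousins, male-sixth-cousins
models = ss+intf
n_pairs = 10000
genome = human-scale
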