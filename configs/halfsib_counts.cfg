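# Segment-count bimodality of maternal vs paternal half-siblings under
# sex-specific maps
kind = halfsib-counts
model = ss+intf
n_pairs = 10000
genome = human-scale
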