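# Haploid (1C) genome masses used to convert DNA mass to genome-equivalent copy numbers.
# Soy, maize and canola values are the ones the screening protocol itself uses for its
# 0.1%-control arithmetic (44 / 18 / 43 copies at 50 ng); the remaining crops carry
# standard plant genome-size compilation values and are needed only by the simulator.
crop	genome_1C_pg
soy	1.13
maize	2.725
canola	1.15
rice	0.50
cotton	2.33
potato	0.85
sugar beet	0.714
wheat	17.33
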