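# Standard biosensing chip: 1000 nm thermal oxide on Si with a protein
# adlayer growing on top, probed in air over the visible working range.
stack.ambient_index = 1.0
stack.substrate_index = 4.0
stack.layers = SiO2:1.46:1000, adlayer:1.45:5
grid.start = 450
grid.stop = 800
grid.points = 512
fit.free = adlayer
noise.sd = 0.002
resolve.replicates = 200
seed = 1
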