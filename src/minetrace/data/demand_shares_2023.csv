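# IEA 2023 clean-energy demand shares for key energy transition minerals,
# fraction of total demand attributable to clean energy technologies.
commodity,share
copper,0.2441
lithium,0.5576
nickel,0.1540
cobalt,0.2977
graphite,0.2789
rare earth elements,0.1720
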