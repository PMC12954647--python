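# Element-specific downstream attenuation distances, km.
# Fill in per-commodity values from Macklin et al. (2023, Science,
# "Impacts of metal mining on river systems"), who modelled the channel
# distance at which metal concentrations fall below Dutch Intervention
# Limits.  Values claiming that provenance must lie within the reported
# 6.5-45.6 km range; commodities left out fall back to 6.5 km (moderate
# scenario) or 45.6 km (severe scenario).
commodity,distance_km,source
# gold,<fill-in>,Macklin et al. 2023
# copper,<fill-in>,Macklin et al. 2023
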