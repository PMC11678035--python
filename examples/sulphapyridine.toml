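# Sulphapyridine bench scenario: inert agarose slab vs the same slab
# enriched with humic acids (apparent binding constant K = 1.92).
# Units are carried in the key names; omitted keys use package defaults.

[geometry]
thickness_mm = 5.0
diameter_mm = 40.0
donor_volume_cm3 = 50.0
acceptor_volume_cm3 = 50.0

[transport]               # inert agarose gel
d_gel_e10_m2_s = 5.20
c0_mg_dm3 = 25.0
epsilon = 1.0

[transport_reactive]      # humic-enriched gel; inherits drug + diffusivity
k_binding = 1.92

[noise]                   # UV/VIS-style read noise
relative_sd = 0.01
absolute_sd_mg_dm3 = 0.02

[simulation]
duration_min = 2300
output_interval_s = 60
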