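class,ef_ug_per_g_per_h,density_g_per_m2
tropical_evergreen_forest,5.9,11
tropical_deciduous_forest,5.9,8
temperate_broadleaf_evergreen_forest,1.77,3
temperate_needleleaf_evergreen_forest,1.77,3
temperate_deciduous_forest,1.77,3
boreal_evergreen_forest,1.77,3
boreal_deciduous_forest,1.77,3
mixed_forest,1.77,3
savanna,5.175,5.78
grassland,1.77,5.2
dense_shrubland,5.1,8.43
open_shrubland,5.25,0.98
tundra,0,0
desert,1,3.1
polar_desert,0,0
cropland,3.45,3.815
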