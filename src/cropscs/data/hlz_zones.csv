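zone_id,zone_name,bt_low,bt_high,precip_low,precip_high,frost_free
1,Polar desert,0,1.5,0,inf,
2,Subpolar dry tundra,1.5,3,0,125,
3,Subpolar moist tundra,1.5,3,125,250,
4,Subpolar wet tundra,1.5,3,250,500,
5,Subpolar rain tundra,1.5,3,500,inf,
6,Boreal desert,3,6,0,125,
7,Boreal dry scrub,3,6,125,250,
8,Boreal moist forest,3,6,250,500,
9,Boreal wet forest,3,6,500,1000,
10,Boreal rain forest,3,6,1000,inf,
11,Cool temperate desert,6,12,0,125,
12,Cool temperate desert scrub,6,12,125,250,
13,Cool temperate steppe,6,12,250,500,
14,Cool temperate moist forest,6,12,500,1000,
15,Cool temperate wet forest,6,12,1000,2000,
16,Cool temperate rain forest,6,12,2000,inf,
17,Warm temperate desert,12,24,0,125,0
18,Warm temperate desert scrub,12,24,125,250,0
19,Warm temperate thorn steppe,12,24,250,500,0
20,Warm temperate dry forest,12,24,500,1000,0
21,Warm temperate moist forest,12,24,1000,2000,0
22,Warm temperate wet forest,12,24,2000,4000,0
23,Warm temperate rain forest,12,24,4000,inf,0
24,Subtropical desert,12,24,0,125,1
25,Subtropical desert scrub,12,24,125,250,1
26,Subtropical thorn woodland,12,24,250,500,1
27,Subtropical dry forest,12,24,500,1000,1
28,Subtropical moist forest,12,24,1000,2000,1
29,Subtropical wet forest,12,24,2000,4000,1
30,Subtropical rain forest,12,24,4000,inf,1
31,Tropical desert,24,inf,0,125,
32,Tropical desert scrub,24,inf,125,250,
33,Tropical thorn woodland,24,inf,250,500,
34,Tropical very dry forest,24,inf,500,1000,
35,Tropical dry forest,24,inf,1000,2000,
36,Tropical moist forest,24,inf,2000,4000,
37,Tropical wet forest,24,inf,4000,8000,
38,Tropical rain forest,24,inf,8000,inf,
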