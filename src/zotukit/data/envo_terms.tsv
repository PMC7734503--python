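label	envo_id
soil	ENVO:00001998
forest soil	ENVO:00002261
grassland soil	ENVO:00005750
agricultural soil	ENVO:00002259
peat soil	ENVO:00005774
rhizosphere	ENVO:00005801
leaf litter	ENVO:01000628
forest biome	ENVO:01000174
grassland biome	ENVO:01000177
desert biome	ENVO:01000179
tundra biome	ENVO:01000180
mangrove biome	ENVO:01000181
marine biome	ENVO:00000447
sediment	ENVO:00002007
marine sediment	ENVO:03000033
compost	ENVO:00002170
freshwater lake	ENVO:00000021
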