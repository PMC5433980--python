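community_id	species
community_01	plant_2
community_01	plant_3
community_01	plant_6
community_02	plant_5
community_02	plant_6
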