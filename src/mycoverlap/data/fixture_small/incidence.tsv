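species	OTU_01	OTU_02	OTU_03	OTU_04	OTU_05	OTU_06	OTU_07	OTU_08	OTU_09	OTU_10	OTU_11	OTU_12	OTU_13	OTU_14	OTU_15	OTU_16	OTU_17	OTU_18	OTU_19	OTU_20
plant_1	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	1	0	0	0	0
plant_2	0	0	0	0	0	1	0	0	1	0	0	1	1	1	0	0	1	1	0	0
plant_3	0	0	0	0	0	0	0	0	0	0	0	0	1	1	0	0	0	0	0	0
plant_4	0	0	0	0	0	0	0	1	0	0	0	1	0	0	0	0	1	0	0	1
plant_5	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0
plant_6	0	0	1	0	1	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0
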