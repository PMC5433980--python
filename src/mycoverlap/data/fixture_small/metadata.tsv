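species	family	locality	n_specimens
plant_1	Triuridaceae	L1	1
plant_1	Triuridaceae	L2	2
plant_2	Burmanniaceae	L1	2
plant_2	Burmanniaceae	L2	2
plant_2	Burmanniaceae	L4	4
plant_3	Burmanniaceae	L1	6
plant_3	Burmanniaceae	L2	4
plant_4	Burmanniaceae	L1	1
plant_4	Burmanniaceae	L2	4
plant_5	Triuridaceae	L1	2
plant_6	Gentianaceae	L1	4
plant_6	Gentianaceae	L2	4
plant_6	Gentianaceae	L3	4
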