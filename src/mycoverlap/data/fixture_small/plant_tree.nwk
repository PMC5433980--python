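(plant_1:1.28222325724,((((plant_2:0,plant_3:0):0.00908303708008,plant_4:0.00908303708008):0.281401166649,plant_5:0.290484203729):0.851138386711,plant_6:1.14162259044):0.140600666799);
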