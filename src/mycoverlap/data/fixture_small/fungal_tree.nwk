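(((OTU_01:2.85284328091,(((OTU_02:0.232783084048,OTU_03:0.232783084048):0.101046939305,(OTU_04:0.212214221554,(OTU_05:0.101593591664,OTU_06:0.101593591664):0.11062062989):0.121615801799):1.09284207725,((OTU_07:1.21405334359,(OTU_08:0.596327335843,OTU_09:0.596327335843):0.617726007745):0.0705325836771,(OTU_10:0.368884571776,(OTU_11:0.286982066063,OTU_12:0.286982066063):0.081902505713):0.915701355489):0.142086173339):1.4261711803):0.0379922401303,((OTU_13:0.366105201208,OTU_14:0.366105201208):0.318688772178,((OTU_15:1.7763568394e-15,OTU_16:1.7763568394e-15):0.580976593108,(OTU_17:0.130143865938,OTU_18:0.130143865938):0.45083272717):0.103817380278):2.20604154765):1.25988654719,(OTU_19:0.0903276773324,OTU_20:0.0903276773324):4.0603943909);
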