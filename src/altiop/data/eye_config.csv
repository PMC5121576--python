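eye_id,vitrectomized,tamponade,fill_fraction,injected_volume_cc
SF6_100,True,SF6_18pct,1.0,
SF6_50,True,SF6_18pct,0.5,
SF6_25,True,SF6_18pct,0.25,
AIR_100,True,room_air,1.0,
PNEUM,False,SF6_100pct_no_vitrectomy,,0.35
BSS,True,BSS,1.0,
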