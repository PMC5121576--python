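eye_id,phase,altitude_m,iop_applanation_mmhg,iop_indentation_mmhg,temperature_c
SF6_100,ascent,2260,16,17,
SF6_100,ascent,2410,19,22,
SF6_100,ascent,2740,27,26,
SF6_100,ascent,3093,31,30,
SF6_100,ascent,3198,32,32,
SF6_100,descent,3090,26,26,
SF6_100,descent,2740,18,17,
SF6_100,descent,2420,18,17,
SF6_100,descent,2260,17,17,
SF6_50,ascent,2260,12,12,
SF6_50,ascent,2410,12,12,
SF6_50,ascent,2740,22,22,
SF6_50,ascent,3093,24,24,
SF6_50,ascent,3198,23,24,
SF6_50,descent,3090,18,20,
SF6_50,descent,2740,16,17,
SF6_50,descent,2420,16,17,
SF6_50,descent,2260,14,13,
SF6_25,ascent,2260,15,16,
SF6_25,ascent,2410,20,21,
SF6_25,ascent,2740,25,26,
SF6_25,ascent,3093,26,26,
SF6_25,ascent,3198,27,28,
SF6_25,descent,3090,26,26,
SF6_25,descent,2740,25,26,
SF6_25,descent,2420,21,22,
SF6_25,descent,2260,20,20,
AIR_100,ascent,2260,16,17,
AIR_100,ascent,2410,20,21,
AIR_100,ascent,2740,25,26,
AIR_100,ascent,3093,25,26,
AIR_100,ascent,3198,26,26,
AIR_100,descent,3090,27,28,
AIR_100,descent,2740,22,22,
AIR_100,descent,2420,20,22,
AIR_100,descent,2260,18,18,
PNEUM,ascent,2260,14,14,
PNEUM,ascent,2410,13,13,
PNEUM,ascent,2740,12,12,
PNEUM,ascent,3093,15,16,
PNEUM,ascent,3198,18,17,
PNEUM,descent,3090,17,17,
PNEUM,descent,2740,18,18,
PNEUM,descent,2420,18,18,
PNEUM,descent,2260,17,17,
BSS,ascent,2260,14,14,
BSS,ascent,2410,11,11,
BSS,ascent,2740,12,13,
BSS,ascent,3093,12,13,
BSS,ascent,3198,15,14,
BSS,descent,3090,14,14,
BSS,descent,2740,17,17,
BSS,descent,2420,19,18,
BSS,descent,2260,14,13,
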