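device_type,design_name,geometry,q_liquid_min_ul_min,q_liquid_max_ul_min,pulse_mode,requires_sheath_liquid,sheath_min_ul_min
GDVN,JKMH_5,30-30-30,5,,<=2.3 MHz,False,
GDVN,MVED_F,30-30-30,5,,<=2.3 MHz,False,
GDVN,JKMH_6,50-60-60,8,,<=2.3 MHz,False,
GDVN,MVED_B,75-60-75,8,,<=1.1 MHz,False,
GDVN,MVED_C,100-90-100,10,,<=0.5 MHz,False,
GDVN,MVED_D,150-100-150,75,,<=0.14 MHz,False,
GDVN,MVED_E,180-145-180,100,,<=0.14 MHz,False,
Micromixer,MVED_Y,100-75-180-300,10,,depends,False,
Micromixer,MVED_Z,200-100-231.7-300,10,,depends,False,
Micromixer,JKMH_10,200-100-100-950,10,,depends,False,
Micromixer,JKMH_10H,100-50-50-950,10,,depends,False,
Mixing-GDVN,MVED_S,100-75-180-2122.3-75-60-75,10,,<=1.1 MHz,False,
Mixing-GDVN,MVED_V,100-75-180-331.8-75-60-75,10,,<=1.1 MHz,False,
DFFN,JKMH_8,100-75-96-445.6-75-70-70,5,,<=1.1 MHz,True,15
HVE,MV_K,50-365-600-20-9,0.3,,10 Hz,False,
HVE,MV_L,75-365-600-20-9,0.3,,10 Hz,False,
HVE,MV_T,100-365-600-20-9,0.3,,10 Hz,False,
Mixing-HVE,MV_I,231.7-100-231.7-2570-100-345-600-20-9,0.3,3,10 Hz,False,
Mixing-HVE,MV_J,231.7-100-231.7-2570-75-345-600-32.5-9,0.3,3,10 Hz,False,
CCT,MV_W,40-200-50-30,0.02,0.8,<=4.5 MHz,False,
CCT,MV_X,10-200-10-20,0.02,0.8,<=4.5 MHz,False,
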