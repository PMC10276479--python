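measure,group,mean,sem,n,unit,note
icp,control,3.4,1.3,8,mmHg,
icp,HFD,5.6,1.2,8,mmHg,
mwa,control,0.10,0.02,7,mmHg,
mwa,HFD,0.18,0.02,7,mmHg,
bodyweight,control,296,3,19,g,
bodyweight,HFD,358,4,22,g,
bmi,control,0.66,0.01,19,g/cm2,
bmi,HFD,0.77,0.01,22,g/cm2,
rout,control,0.44,0.06,5,mmHg.min/ul,
rout,HFD,0.67,0.04,5,mmHg.min/ul,
vp,control,5.14,1.38,6,ul/min,
vp,HFD,5.06,0.91,7,ul/min,
brain_water,control,77.6,0.3,5,%,
brain_water,HFD,77.6,0.3,5,%,
icp_tt,vehicle,2.50,0.11,6,mmHg,printed SEM '11' corrected to 0.11 (apparent typo)
icp_tt,TT,3.79,0.29,4,mmHg,
dye_slope,vehicle,0.13,0.05,5,a.u./min,
dye_slope,TT,0.24,0.05,4,a.u./min,
brain_water_tt,vehicle,78.4,0.3,5,%,
brain_water_tt,TT,78.5,0.2,5,%,
influx_ouabain_sensitive,vehicle,19.2,3.8,4,1e3 cpm,
influx_ouabain_sensitive,TT,14.7,6.4,4,1e3 cpm,
efflux_k_bumetanide_sensitive,vehicle,0.32,0.03,5,1/min,
efflux_k_bumetanide_sensitive,TT,0.38,0.05,6,1/min,
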