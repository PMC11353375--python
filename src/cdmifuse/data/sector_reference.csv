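sector,area_expected_cm2,area_unregistered_cm2,area_unregistered_sd,area_registered_cm2,area_registered_sd,adc_expected,adc_expected_sd,adc_unregistered,adc_unregistered_sd,adc_registered,adc_registered_sd
1,16.2,15.6,1.6,15.1,1.6,800,130,730,80,660,70
2,16.2,21.2,2.2,14.7,1.5,1400,100,1310,140,1330,70
3,16.2,22.6,2.3,13.0,1.4,1110,110,1120,120,1130,70
4,16.2,21.1,2.2,14.9,1.5,800,130,550,200,530,100
5,16.2,15.1,1.6,16.5,1.7,1400,100,1370,80,1350,40
6,16.2,9.8,1.0,17.1,1.8,1110,110,1260,180,1230,80
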