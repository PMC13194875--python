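sample,analyte,mean,sd,unit
mexico,CF,8491.40,64.22,mg/kg
mexico,diCGA_35,195.23,1.21,mg/kg
mexico,CGA_5,675.62,3.95,mg/kg
mexico,CGA_3,206.34,0.40,mg/kg
mexico,TR,321.67,8.96,mg/kg
mexico,FA,28.35,0.36,mg/kg
mexico,TA,41.24,0.95,mg/kg
mexico,CA,134.41,6.19,mg/kg
mexico,AA,403.66,1.14,mg/kg
mexico,LP,11.00,1.35,%w/w
rwanda,CF,8615.33,84.20,mg/kg
rwanda,diCGA_35,201.66,0.53,mg/kg
rwanda,CGA_5,722.17,3.27,mg/kg
rwanda,CGA_3,218.64,1.61,mg/kg
rwanda,TR,305.83,7.26,mg/kg
rwanda,FA,34.96,2.49,mg/kg
rwanda,TA,40.00,0.80,mg/kg
rwanda,CA,125.17,4.1,mg/kg
rwanda,AA,456.24,4.53,mg/kg
rwanda,LP,12.30,1.84,%w/w
nicaragua,CF,15258.71,57.04,mg/kg
nicaragua,diCGA_35,310.24,1.18,mg/kg
nicaragua,CGA_5,980.82,1.58,mg/kg
nicaragua,CGA_3,300.11,0.29,mg/kg
nicaragua,TR,227.18,10.85,mg/kg
nicaragua,FA,32.31,0.73,mg/kg
nicaragua,TA,43.72,1.55,mg/kg
nicaragua,CA,258.96,1.96,mg/kg
nicaragua,AA,671.21,2.01,mg/kg
nicaragua,LP,7.10,1.56,%w/w
indonesia,CF,16607.39,12.48,mg/kg
indonesia,diCGA_35,329.10,1.09,mg/kg
indonesia,CGA_5,1050.11,2.21,mg/kg
indonesia,CGA_3,315.08,1.83,mg/kg
indonesia,TR,220.58,10.55,mg/kg
indonesia,FA,33.29,2.42,mg/kg
indonesia,TA,42.18,1.38,mg/kg
indonesia,CA,280.93,3.56,mg/kg
indonesia,AA,693.39,7.04,mg/kg
indonesia,LP,10.20,2.83,%w/w
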