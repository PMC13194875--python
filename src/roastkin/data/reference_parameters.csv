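sample,reaction,k_ref,E_a
mexico,1,2.3763e-05,109.9181
mexico,2,1.4466e-04,109.9752
mexico,3,1.0922e-05,104.9629
mexico,4,5.2319e-04,104.9773
mexico,5,1.1896e-06,104.9766
mexico,6,1.0151e-03,105.0229
mexico,7,3.7263e-05,104.9297
mexico,8,1.0000e-06,134.8449
mexico,9,9.4181e-04,110.0308
mexico,10,9.9865e-04,60.0827
mexico,11,4.2515e-04,100.0092
mexico,12,4.2419e-04,100.0092
mexico,13,5.0386e-04,100.0018
mexico,14,1.9548e-02,100.1420
mexico,15,1.0000e-03,100.1980
rwanda,1,1.5166e-05,124.6180
rwanda,2,2.8421e-04,90.8344
rwanda,3,9.1560e-04,87.8731
rwanda,4,4.7929e-04,112.6491
rwanda,5,1.9342e-06,115.2129
rwanda,6,1.7889e-03,105.7871
rwanda,7,6.2401e-04,120.9254
rwanda,8,1.1517e-06,145.8624
rwanda,9,1.4146e-05,126.8107
rwanda,10,5.1406e-05,51.7517
rwanda,11,9.0666e-04,77.5419
rwanda,12,5.1567e-04,96.2164
rwanda,13,3.6364e-04,112.1700
rwanda,14,2.4444e-02,93.3901
rwanda,15,9.5798e-04,105.9417
nicaragua,1,3.5328e-05,122.3157
nicaragua,2,1.7855e-04,100.0190
nicaragua,3,7.9492e-05,121.3410
nicaragua,4,5.0132e-04,96.7950
nicaragua,5,1.4989e-06,115.6815
nicaragua,6,8.2930e-02,122.5968
nicaragua,7,8.8913e-06,123.4736
nicaragua,8,1.0000e-06,109.2285
nicaragua,9,1.3745e-02,139.7457
nicaragua,10,1.0000e-03,48.1179
nicaragua,11,3.8697e-04,95.4996
nicaragua,12,4.6803e-04,93.8043
nicaragua,13,2.2884e-04,121.7768
nicaragua,14,2.4683e-02,103.2257
nicaragua,15,7.9041e-04,111.7874
indonesia,1,5.0141e-05,109.9405
indonesia,2,1.4209e-04,109.9741
indonesia,3,1.1630e-04,104.9826
indonesia,4,4.1395e-04,105.0052
indonesia,5,3.1343e-05,105.0028
indonesia,6,7.6982e-04,105.0231
indonesia,7,2.6232e-05,104.9468
indonesia,8,2.6444e-05,135.0001
indonesia,9,3.8173e-04,110.0046
indonesia,10,3.6369e-05,59.9898
indonesia,11,3.5367e-04,100.0035
indonesia,12,4.2106e-04,100.0091
indonesia,13,4.9929e-04,99.9926
indonesia,14,2.5734e-02,100.1612
indonesia,15,5.0210e-05,100.0466
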