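sample,marker,clock_time,temp_C
mexico,charge,0:00,180
mexico,turning_point,1:33,88.5
mexico,yellow,5:20,151
mexico,first_crack,10:05,202
mexico,drop,13:03,214.8
rwanda,charge,0:00,182
rwanda,turning_point,1:31,88
rwanda,yellow,5:15,150
rwanda,first_crack,10:06,200
rwanda,drop,12:56,213
nicaragua,charge,0:00,190
nicaragua,turning_point,1:39,77.6
nicaragua,yellow,6:35,156
nicaragua,first_crack,11:56,201
nicaragua,drop,15:20,230
indonesia,charge,0:00,185.6
indonesia,turning_point,1:38,77.4
indonesia,yellow,6:55,156
indonesia,first_crack,11:52,203
indonesia,drop,14:56,228
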