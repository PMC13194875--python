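species,variety,low,high,unit
CF,arabica,0.8,1.4,%w/w
TA,arabica,0.02,0.02,%w/w
SUC,arabica,6.0,9.0,%w/w
FRU,arabica,0.05,0.05,%w/w
GLC,arabica,0.05,0.05,%w/w
FAM,arabica,0.5,0.5,%w/w
AA,arabica,0.02,0.02,%w/w
CA,arabica,0.2,0.6,%w/w
TR,arabica,0.6,1.3,%w/w
CGA,arabica,4.0,8.0,%w/w
FA,arabica,0.03,0.09,%w/w
LP,arabica,10,17,%w/w
CF,robusta,1.7,4.0,%w/w
TA,robusta,0.02,0.02,%w/w
SUC,robusta,0.9,4.0,%w/w
FRU,robusta,0.2,0.2,%w/w
GLC,robusta,0.2,0.2,%w/w
FAM,robusta,0.8,1.0,%w/w
AA,robusta,0.025,0.025,%w/w
CA,robusta,0.2,0.7,%w/w
TR,robusta,0.3,0.9,%w/w
CGA,robusta,7.0,10.0,%w/w
FA,robusta,0.04,0.12,%w/w
LP,robusta,11,11,%w/w
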