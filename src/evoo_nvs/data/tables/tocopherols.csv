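lo,hi,cohort,percent
0,100,2013,0.0
0,100,2014,2.8
100,200,2013,18.2
100,200,2014,54.2
200,300,2013,61.6
200,300,2014,31.7
300,400,2013,17.8
300,400,2014,11.1
400,500,2013,0.0
400,500,2014,0.0
500,,2013,2.4
500,,2014,0.3
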