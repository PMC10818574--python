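lo,hi,cohort,percent
0,0.15,2013,4.8
0,0.15,2014,2.7
0,0.15,commercial,8.9
0.15,0.25,2013,74.1
0.15,0.25,2014,15.0
0.15,0.25,commercial,44.5
0.25,0.4,2013,19.4
0.25,0.4,2014,36.4
0.25,0.4,commercial,34.9
0.4,0.5,2013,0.8
0.4,0.5,2014,10.0
0.4,0.5,commercial,8.9
0.5,0.6,2013,0.3
0.5,0.6,2014,9.1
0.5,0.6,commercial,2.1
0.6,0.8,2013,0.0
0.6,0.8,2014,12.7
0.6,0.8,commercial,0.7
0.8,,2013,0.6
0.8,,2014,14.1
0.8,,commercial,0.0
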