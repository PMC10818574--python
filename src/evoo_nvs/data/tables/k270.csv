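lo,hi,cohort,percent
0,0.1,2013,3.4
0,0.1,2014,3.9
0,0.1,commercial,3.4
0.1,0.13,2013,35.3
0.1,0.13,2014,17.1
0.1,0.13,commercial,32.0
0.13,0.17,2013,51.0
0.13,0.17,2014,51.2
0.13,0.17,commercial,43.5
0.17,0.2,2013,9.4
0.17,0.2,2014,23.7
0.17,0.2,commercial,15.0
0.2,0.22,2013,0.9
0.2,0.22,2014,1.3
0.2,0.22,commercial,3.4
0.22,,2013,0.0
0.22,,2014,2.6
0.22,,commercial,2.7
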