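lo,hi,cohort,percent
0,1.5,2013,5.5
0,1.5,2014,1.3
0,1.5,commercial,0.0
1.5,1.65,2013,20.9
1.5,1.65,2014,9.2
1.5,1.65,commercial,3.4
1.65,1.85,2013,56.1
1.65,1.85,2014,34.2
1.65,1.85,commercial,24.5
1.85,2.15,2013,16.6
1.85,2.15,2014,39.5
1.85,2.15,commercial,49.0
2.15,2.5,2013,0.9
2.15,2.5,2014,13.2
2.15,2.5,commercial,17.7
2.5,,2013,0.0
2.5,,2014,2.6
2.5,,commercial,5.4
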