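lo,hi,cohort,percent
0,3.0,2013,7.1
0,3.0,2014,2.9
0,3.0,commercial,0.0
3.0,6.0,2013,65.7
3.0,6.0,2014,30.9
3.0,6.0,commercial,15.0
6.0,10.0,2013,24.6
6.0,10.0,2014,45.7
6.0,10.0,commercial,65.3
10.0,15.0,2013,2.3
10.0,15.0,2014,17.1
10.0,15.0,commercial,17.7
15.0,20.0,2013,0.3
15.0,20.0,2014,2.9
15.0,20.0,commercial,2.0
20.0,,2013,0.0
20.0,,2014,0.5
20.0,,commercial,0.0
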