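lo,hi,cohort,percent
0,50,2013,0.2
0,50,2014,0.0
50,150,2013,5.0
50,150,2014,6.9
150,250,2013,15.6
150,250,2014,10.6
250,350,2013,23.9
250,350,2014,30.5
350,500,2013,31.9
350,500,2014,42.2
500,650,2013,18.4
500,650,2014,8.2
650,800,2013,4.3
650,800,2014,1.2
800,1000,2013,0.7
800,1000,2014,0.2
1000,,2013,0.0
1000,,2014,0.2
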