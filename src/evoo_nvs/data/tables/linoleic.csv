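lo,hi,cohort,percent
0,2.5,2013,0.0
0,2.5,2014,0.0
0,2.5,commercial,0.0
0,2.5,Australia,0.0
0,2.5,Greece,0.0
0,2.5,Italy,0.0
0,2.5,Portugal,0.0
0,2.5,Spain,0.0
0,2.5,Tunisia,0.0
2.5,6,2013,34.1
2.5,6,2014,48.6
2.5,6,commercial,18.3
2.5,6,Australia,18.8
2.5,6,Greece,8.3
2.5,6,Italy,1.6
2.5,6,Portugal,9.7
2.5,6,Spain,56.4
2.5,6,Tunisia,0.0
6,11,2013,58.4
6,11,2014,46.9
6,11,commercial,78.0
6,11,Australia,50.0
6,11,Greece,91.7
6,11,Italy,96.9
6,11,Portugal,66.1
6,11,Spain,35.6
6,11,Tunisia,0.0
11,16,2013,4.6
11,16,2014,2.8
11,16,commercial,3.7
11,16,Australia,31.3
11,16,Greece,0.0
11,16,Italy,1.6
11,16,Portugal,24.2
11,16,Spain,8.1
11,16,Tunisia,64.3
16,21,2013,2.9
16,21,2014,1.7
16,21,commercial,0.0
16,21,Australia,0.0
16,21,Greece,0.0
16,21,Italy,0.0
16,21,Portugal,0.0
16,21,Spain,0.0
16,21,Tunisia,35.7
21,,2013,0.0
21,,2014,0.0
21,,commercial,0.0
21,,Australia,0.0
21,,Greece,0.0
21,,Italy,0.0
21,,Portugal,0.0
21,,Spain,0.0
21,,Tunisia,0.0
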