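lo,hi,cohort,percent
0,7.5,2013,0.0
0,7.5,2014,0.0
0,7.5,commercial,0.0
0,7.5,Australia,0.0
0,7.5,Greece,0.0
0,7.5,Italy,0.0
0,7.5,Portugal,0.0
0,7.5,Spain,0.0
0,7.5,Tunisia,0.0
7.5,11,2013,0.0
7.5,11,2014,0.0
7.5,11,commercial,0.0
7.5,11,Australia,0.0
7.5,11,Greece,0.0
7.5,11,Italy,0.0
7.5,11,Portugal,0.0
7.5,11,Spain,0.0
7.5,11,Tunisia,0.0
11,15,2013,56.6
11,15,2014,81.0
11,15,commercial,58.9
11,15,Australia,62.5
11,15,Greece,77.8
11,15,Italy,90.5
11,15,Portugal,17.7
11,15,Spain,63.5
11,15,Tunisia,7.1
15,20,2013,42.2
15,20,2014,18.4
15,20,commercial,41.1
15,20,Australia,37.5
15,20,Greece,22.2
15,20,Italy,9.5
15,20,Portugal,82.3
15,20,Spain,36.5
15,20,Tunisia,78.6
20,25,2013,1.2
20,25,2014,0.6
20,25,commercial,0.0
20,25,Australia,0.0
20,25,Greece,0.0
20,25,Italy,0.0
20,25,Portugal,0.0
20,25,Spain,0.0
20,25,Tunisia,14.3
25,,2013,0.0
25,,2014,0.0
25,,commercial,0.0
25,,Australia,0.0
25,,Greece,0.0
25,,Italy,0.0
25,,Portugal,0.0
25,,Spain,0.0
25,,Tunisia,0.0
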