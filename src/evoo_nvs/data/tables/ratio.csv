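lo,hi,cohort,percent
0,2.4,2013,0
0,2.4,2014,1
0,2.4,commercial,0
0,2.4,Australia,0
0,2.4,Greece,0
0,2.4,Italy,0
0,2.4,Portugal,0
0,2.4,Spain,0
0,2.4,Tunisia,0
2.4,4.5,2013,3
2.4,4.5,2014,2
2.4,4.5,commercial,3
2.4,4.5,Australia,6
2.4,4.5,Greece,0
2.4,4.5,Italy,0
2.4,4.5,Portugal,0
2.4,4.5,Spain,2
2.4,4.5,Tunisia,100
4.5,7.0,2013,14
4.5,7.0,2014,5
4.5,7.0,commercial,17
4.5,7.0,Australia,31
4.5,7.0,Greece,6
4.5,7.0,Italy,6
4.5,7.0,Portugal,66
4.5,7.0,Spain,14
4.5,7.0,Tunisia,0
7.0,14.0,2013,82
7.0,14.0,2014,92
7.0,14.0,commercial,76
7.0,14.0,Australia,63
7.0,14.0,Greece,94
7.0,14.0,Italy,92
7.0,14.0,Portugal,27
7.0,14.0,Spain,66
7.0,14.0,Tunisia,0
14.0,34.0,2013,1
14.0,34.0,2014,0
14.0,34.0,commercial,5
14.0,34.0,Australia,0
14.0,34.0,Greece,0
14.0,34.0,Italy,2
14.0,34.0,Portugal,6
14.0,34.0,Spain,18
14.0,34.0,Tunisia,0
34.0,,2013,0
34.0,,2014,0
34.0,,commercial,0
34.0,,Australia,0
34.0,,Greece,0
34.0,,Italy,0
34.0,,Portugal,0
34.0,,Spain,0
34.0,,Tunisia,0
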