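lo,hi,cohort,percent
0,55,2013,1
0,55,2014,0
0,55,commercial,0
0,55,Australia,0
0,55,Greece,0
0,55,Italy,0
0,55,Portugal,0
0,55,Spain,0
0,55,Tunisia,0
55,63,2013,2
55,63,2014,2
55,63,commercial,1
55,63,Australia,0
55,63,Greece,0
55,63,Italy,0
55,63,Portugal,0
55,63,Spain,1
55,63,Tunisia,79
63,71,2013,9
63,71,2014,3
63,71,commercial,9
63,71,Australia,31
63,71,Greece,0
63,71,Italy,3
63,71,Portugal,50
63,71,Spain,11
63,71,Tunisia,21
71,78,2013,68
71,78,2014,53
71,78,commercial,76
71,78,Australia,50
71,78,Greece,97
71,78,Italy,56
71,78,Portugal,42
71,78,Spain,46
71,78,Tunisia,0
78,85,2013,19
78,85,2014,42
78,85,commercial,14
78,85,Australia,19
78,85,Greece,3
78,85,Italy,41
78,85,Portugal,8
78,85,Spain,42
78,85,Tunisia,0
85,,2013,0
85,,2014,0
85,,commercial,0
85,,Australia,0
85,,Greece,0
85,,Italy,0
85,,Portugal,0
85,,Spain,0
85,,Tunisia,0
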