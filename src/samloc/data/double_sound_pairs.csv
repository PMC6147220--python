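# Double-sound speaker-pair configuration, version 1.
# 24 elevation pairs on the 5-degree cardinal-axis grid, -45..+75 deg.
# Separations tile {15,30,45,60,75} deg with counts {5,5,5,5,4};
# the pairs use exactly 17 unique elevations (the single-sound locations).
low_el,high_el,separation_deg
-40,-25,15
-25,-10,15
5,20,15
35,50,15
50,65,15
30,60,30
45,75,30
-45,-15,30
0,30,30
15,45,30
-45,0,45
-30,15,45
30,75,45
0,45,45
15,60,45
-45,15,60
-30,30,60
0,60,60
15,75,60
-15,45,60
-45,30,75
-30,45,75
-15,60,75
0,75,75
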