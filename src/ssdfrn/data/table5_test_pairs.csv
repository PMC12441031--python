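sample,actual,estimated
0,23.314,25.475
1,13.628,14.01
2,14.103,15.244
3,10.036,12.005
4,20.418,22.799
5,12.205,14.859
6,12.006,12.537
7,12.796,12.546
8,10.568,11.705
9,14.34,13.724
10,28.298,27.128
11,20.841,21.265
12,22.841,23.081
13,19.479,19.353
14,28.834,26.593
15,20.671,21.758
16,21.057,21.673
17,28.526,29.987
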