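# Synthetic digitized auxin-reporter staining profile (densitometry
# emulation generated from the basic-set model solution: affine
# response, background, blur, 4% multiplicative noise; NOT measured
# data). Columns: cell_index, intensity
1,158.904
2,173.419
3,155.394
4,156.053
5,154.877
6,150.110
7,148.492
8,168.155
9,178.172
10,176.877
11,231.859
12,197.793
13,107.033
14,53.316
15,36.593
16,33.710
17,33.968
18,31.125
19,33.565
20,34.741
21,34.752
22,32.719
23,34.428
24,31.177
25,33.240
26,34.168
27,31.868
28,33.680
29,36.243
30,37.580
31,35.193
32,35.381
33,33.042
34,32.807
35,32.635
36,35.456
37,35.867
38,34.014
39,33.328
40,35.529
41,35.724
42,35.214
43,37.320
44,35.501
45,35.656
46,34.278
47,36.181
48,38.049
49,36.310
50,36.414
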