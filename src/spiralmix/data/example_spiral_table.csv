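individual,group,pr_spiral,c_hat
1,incremental,0.11,0
2,incremental,0.91,4
3,entity,0.24,0
4,incremental,0.09,0
5,entity,0.10,0
6,incremental,0.04,0
7,incremental,0.12,0
8,incremental,0.18,0
9,incremental,0.04,0
10,entity,0.10,0
11,incremental,0.09,0
12,incremental,0.22,0
13,entity,0.05,0
14,entity,0.61,3
15,incremental,0.38,0
16,entity,0.33,0
17,incremental,0.14,0
18,entity,0.97,4
19,entity,0.99,9
20,entity,0.95,4
21,entity,1.00,4
22,entity,1.00,3
23,incremental,0.02,0
24,entity,0.34,0
25,incremental,0.08,0
26,entity,1.00,3
27,incremental,0.12,0
28,entity,0.94,1
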