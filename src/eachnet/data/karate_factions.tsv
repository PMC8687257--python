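# Zachary karate club: two-faction political alignment before the split.
# Actor 9 sided with the administrator's faction although he later joined
# the instructor's club; the alignment is the standard ground truth whose
# two-block modularity is 0.3715.
1	1
2	1
3	1
4	1
5	1
6	1
7	1
8	1
9	2
10	2
11	1
12	1
13	1
14	1
15	2
16	2
17	1
18	1
19	2
20	1
21	2
22	1
23	2
24	2
25	2
26	2
27	2
28	2
29	2
30	2
31	2
32	2
33	2
34	2
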