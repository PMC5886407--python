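# loop initiation free energies by unpaired size, kcal/mol
size	hairpin	bulge	internal
1	NA	3.80	NA
2	NA	2.80	1.50
3	5.40	3.20	1.60
4	5.60	3.60	1.70
5	5.70	4.00	1.80
6	5.40	4.40	2.00
7	6.00	4.57	2.20
8	5.50	4.71	2.30
9	6.40	4.84	2.40
10	6.51	4.95	2.51
11	6.62	5.05	2.62
12	6.71	5.15	2.71
13	6.80	5.23	2.80
14	6.88	5.31	2.88
15	6.95	5.39	2.95
16	7.02	5.46	3.02
17	7.09	5.52	3.09
18	7.15	5.59	3.15
19	7.21	5.64	3.21
20	7.26	5.70	3.26
21	7.31	5.75	3.31
22	7.36	5.80	3.36
23	7.41	5.85	3.41
24	7.46	5.90	3.46
25	7.50	5.94	3.50
26	7.54	5.98	3.54
27	7.59	6.02	3.59
28	7.62	6.06	3.62
29	7.66	6.10	3.66
30	7.70	6.14	3.70
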