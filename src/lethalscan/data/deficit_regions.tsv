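breed	name	chromosome	interval_mb	expected	observed	freq_pct	p
HOL	BY	21	20.2-22.3	49	0	3.6	2.6E-12
HOL	HH1	5	61.4-66.2	18	0	2.6	2.2E-05
HOL	HH2	1	93.0-97.4	14	3	1.7	3.3E-03
HOL	HH3	8	94.0-96.5	21	0	2.5	4.6E-06
HOL	HH4	1	1.9-3.3	49	0	3.6	2.6E-12
HOL	HH5	3	45.8-47.6	68	24	3.9	9.5E-08
HOL	HH6	3	49.4-52.6	91	38	4.6	2.8E-08
HOL	HH7	6	51.6-52.6	202	100	6.9	7.1E-13
HOL	HH8	7	78.8-80.1	15	0	2.1	1.1E-04
HOL	HH9	10	74.8-77.0	40	13	2.9	2.0E-05
HOL	HH10	11	31.5-33.2	24	1	2.2	2.7E-06
HOL	HH11	12	2.0-3.6	75	35	3.2	3.9E-06
HOL	HH12	15	77.3-79.4	127	54	5.5	9.3E-11
HOL	HH13	18	56.4-58.4	32	5	3.7	1.8E-06
HOL	HH14	19	42.7-43.9	40	8	2.4	4.2E-07
HOL	HH15	20	58.5-59.6	68	25	2.7	1.8E-07
HOL	HH16	26	10.4-12.8	26	2	2.0	2.5E-06
HOL	HH17	26	24.9-26.0	33	5	1.8	1.1E-06
MON	MH1	19	27.6-29.4	131	0	9.0	2.5E-30
MON	MH2	29	27.9-29.1	80	1	7.0	1.0E-18
MON	MH3	2	31.5-32.8	39	9	5.1	1.6E-06
MON	MH4	4	52.0-53.2	21	1	3.5	1.3E-05
MON	MH5	6	73.3-74.4	122	14	7.1	1.4E-22
MON	MH6	7	80.1-81.7	21	3	2.6	8.6E-05
MON	MH7	9	84.6-86.4	126	21	7.1	8.4E-21
MON	MH8	13	76.4-77.6	26	3	3.5	6.5E-06
MON	MH9	20	24.2-25.7	33	6	2.6	2.6E-06
MON	MH10	24	22.9-24.6	26	0	2.5	3.4E-07
MON	MH11	24	33.4-34.6	159	29	7.2	6.4E-25
NOR	NH1	24	38.1-39.2	12	0	1.8	5.3E-04
NOR	NH2	1	145.7-146.8	49	14	3.8	5.7E-07
NOR	NH3	4	92.3-93.8	41	10	5.9	1.3E-06
NOR	NH4	6	37.7-38.9	38	12	5.2	2.5E-05
NOR	NH5	7	3.6-4.6	58	20	1.9	6.0E-07
NOR	NH6	15	59.8-61.1	45	17	1.9	3.0E-05
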