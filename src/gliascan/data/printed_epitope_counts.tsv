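epitope	group_6	group_7	group_3	group_5	group_8	group_9	group_10	printed_sum
DQ2-γ-VIIb	701	144	72	230	57	1257	50	2511
DQ2-γ-VI	224	0	0	0	38	678	50	990
DQ2-glia-γ2a	140	30	36	59	38	684	0	987
DQ2-γ-II	136	0	41	125	0	293	61	656
DQ2-γ-I	120	38	41	115	19	293	61	567
DQ2-γ-VIIa	0	0	0	115	19	0	0	134
DQ2-γ-IV	0	0	0	0	0	0	61	61
DQ2-γ-III	0	0	0	0	0	0	50	50
DQ2-glia-γ2b	0	0	0	0	0	0	50	50
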