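group	locus	n_transcripts
group_6	Gli-A1	140
group_7	Gli-A1	38
group_3	Gli-B1	41
group_5	Gli-B1	125
group_8	Gli-B1	19
group_9	Gli-D1	293
group_10	Gli-D1	61
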