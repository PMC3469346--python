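label	alt_label	core
DQ2-γ-VIIb	DQ2.5-glia-γ4c	QQPQQPFPQ
DQ2-γ-VI	DQ2.5-glia-γ5	QQPFPQQPQ
DQ2-glia-γ2a		FPQQPQQPF
DQ2-γ-II	DQ2.5-glia-γ2	IQPQQPAQL
DQ2-γ-I	DQ2.5-glia-γ1	PQQSFPQQQ
DQ2-γ-VIIa	DQ2.5-glia-γ4b	PQPQQQFPQ
DQ2-γ-IV	DQ2.5-glia-γ4a	SQPQQQFPQ
DQ2-γ-III	DQ2.5-glia-γ3	QQPQQPYPQ
DQ2-glia-γ2b		YPQQPQQPF
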