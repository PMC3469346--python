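peptide	moderate_positions	source
QPQQPQQSFPQQQQPLI	5	DQ2-γ-I variant 1
QPQQPQQSFPQQQQLMI	5,11,12,13	DQ2-γ-I variant 2
QPQQPQQPFPQQQQPLI		DQ2-γ-I variant 3
QPQQPQQSFPQQQQPAI	5	DQ2-γ-I variant 4
QPQQPQQSFPQQQPSLI	5	DQ2-γ-I variant 5
QPQQPQQSSPQQQQLLI	11,12,13	DQ2-γ-I variant 6
QSQQPQQSSPQQQQLLI	11,12,13	DQ2-γ-I variant 7
QPQQSQQSSPQQQQLLI	11,12,13	DQ2-γ-I variant 8
QPQQPQQSFPQQQQWMI	5,11,12,13	DQ2-γ-I variant 9
QPQQPQQSFPQQQRPFI	5	DQ2-γ-I variant 10
QPQQPQQSFPQQQRSFI	5,12	DQ2-γ-I variant 11
QPQQPQQSFPQQQPPFI	5	DQ2-γ-I variant 12
QPQQPQQSFPQQQPPLI	5	DQ2-γ-I variant 13
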