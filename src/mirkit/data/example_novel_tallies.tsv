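library	unique_to_library	present_in_2_or_more	printed_total
QF1160MB	33	52	85
MELB	0	16	16
MM653	17	33	50
D20	21	51	72
MM386	26	64	90
MM426	16	39	55
MM466	10	45	55
MM603	20	40	60
MM472	11	33	44
D10	4	22	26
D11	6	27	33
MEL202	9	25	34
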