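miRNA	QF1160MB	MELB	MM653	D20	MM386	MM426	MM466	MM603	MM472	D10	D11	MEL202
hsa-let-7a	2	2	1	2	1	2	3	2	2	2	2	2
hsa-let-7b	5	3	2	3	5	3		4	3	4	5	5
hsa-let-7d		9						8		6	7	7
hsa-let-7e	6	4	8									9
hsa-let-7f	1	1	3	1	3	1	7	1	1	1	1	1
hsa-let-7g		10				10		7			4	8
hsa-let-7i	3	5	10	6	6				9	8	6
hsa-miR-103	10			8	7	6	2	3	6		3	6
hsa-miR-140-3p									4	9	9	10
hsa-miR-146a						8
hsa-miR-181a					10
hsa-miR-185								10
hsa-miR-21			6	5	4	4	8	9	5
hsa-miR-211											10
hsa-miR-221			4	7	9
hsa-miR-222			9
hsa-miR-25						9	10			10	8
hsa-miR-29a	9	6	7	4	2	5	1	5	7	3
hsa-miR-320a	4	8	5	9					8	7		3
hsa-miR-378	7	7		10		7	4			5		4
hsa-miR-423-5p	8				8		5		10
hsa-miR-886-5p							6
hsa-miR-92a							9	6
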