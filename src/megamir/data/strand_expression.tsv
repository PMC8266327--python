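gene_id	arm	mean_rpm_young	regulation
MIR1193	3p	35.5	down
MIR1193	5p	3.3	down
MIR127	3p	3203.1	down
MIR127	5p	108.2	down
MIR136	3p	141.4	down
MIR136	5p	29.8	down
MIR299a	3p	211.3	down
MIR299a	5p	18.6	down
MIR329	3p	54.7	down
MIR329	5p	94.2	down
MIR369	3p	78.9	down
MIR369	5p	23.9	down
MIR377	3p	5.9	down
MIR377	5p	4.0	down
MIR379	3p	86.0	down
MIR379	5p	1472.5	down
MIR382	3p	197.4	down
MIR382	5p	214.2	down
MIR409	3p	394.0	down
MIR409	5p	132.2	down
MIR411	3p	142.4	down
MIR411	5p	688.1	down
MIR434	3p	293.6	down
MIR434	5p	560.2	down
MIR540	3p	78.7	down
MIR540	5p	1.4	down
MIR673	3p	4.4	down
MIR673	5p	10.7	down
MIR341	3p	121.6	down
MIR341	5p	3.0	steady
MIR370	3p	104.4	down
MIR370	5p	2.2	steady
MIR376b	3p	38.1	down
MIR376b	5p	4.3	steady
MIR410	3p	55.7	down
MIR410	5p	4.3	steady
MIR494	3p	363.7	down
MIR494	5p	1.5	steady
MIR154	3p	11.2	steady
MIR154	5p	12.7	down
MIR337	3p	7.8	steady
MIR337	5p	279.0	down
MIR541	3p	2.8	steady
MIR541	5p	1464.9	down
MIR679	3p	1.6	steady
MIR679	5p	13.5	down
MIR376a	3p	1.3	steady
MIR376a	5p	5.5	steady
MIR380	3p	13.7	steady
MIR380	5p	12.4	steady
MIR412	3p	0.9	steady
MIR412	5p	5.8	steady
MIR431	3p	13.2	steady
MIR431	5p	29.5	steady
MIR433	3p	120.5	steady
MIR433	5p	1.8	steady
MIR485	3p	62.7	steady
MIR485	5p	15.9	steady
MIR493	3p	8.4	steady
MIR493	5p	39.7	steady
MIR667	3p	11.2	steady
MIR667	5p	8.6	steady
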