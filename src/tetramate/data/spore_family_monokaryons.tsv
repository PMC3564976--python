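strain	ploidy	mat_a	mat_b	flags	country	locality
R1	monokaryon	A1	B3
R2	monokaryon	A1	B3
R7	monokaryon	A1	B3
R18	monokaryon	A1	B3
R4	monokaryon	A3	B2
R13	monokaryon	A3	B2
R19	monokaryon	A3	B2
R22	monokaryon	A3	B2
R12	monokaryon	A1	B2
R14	monokaryon	A1	B2
R20	monokaryon	A1	B2
R21	monokaryon	A1	B2
R9	monokaryon	A3	B3
R10	monokaryon	A3	B3
R16	monokaryon	A3	B3
R17	monokaryon	A3	B3
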