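strain	functional_a	functional_b	proxy_a	proxy_b
S3.3	A1	B4	A2	B2
S3.9	A2	B3	A3	B3
S3.10	A1	B3	A2	B3
S7.3	A1	B1	A2	B4
S7.8	A1	B2	A2	B1
S7.9	A2	B2	A3	B1
S12.5	A1	B5	A2	B3
S5.2	A4	B4	A3	B2
S5.3	A4	B1	A3	B4
S5.13	A3	B4	A1	B2
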