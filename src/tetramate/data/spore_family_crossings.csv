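,R1,R2,R7,R18,R4,R13,R19,R22,R12,R14,R20,R21,R9,R10,R16,R17
R1,,-,-,-,+,+,+,+,-,-,-,-,-,-,-,-
R2,,,-,-,+,+,+,?,-,-,-,-,-,-,-,-
R7,,,,-,+,+,+,+,-,-,-,-,-,-,-,-
R18,,,,,+,+,+,+,-,-,-,-,-,-,-,-
R4,,,,,,-,-,-,-,-,-,-,-,-,-,-
R13,,,,,,,-,-,-,-,-,-,-,-,-,-
R19,,,,,,,,-,-,-,-,-,-,-,-,-
R22,,,,,,,,,-,-,-,-,-,-,-,-
R12,,,,,,,,,,-,-,-,+,+,+,+
R14,,,,,,,,,,,-,-,+,+,+,+
R20,,,,,,,,,,,,-,+,+,+,+
R21,,,,,,,,,,,,,+,+,+,+
R9,,,,,,,,,,,,,,-,-,-
R10,,,,,,,,,,,,,,,-,-
R16,,,,,,,,,,,,,,,,-
R17,,,,,,,,,,,,,,,,
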