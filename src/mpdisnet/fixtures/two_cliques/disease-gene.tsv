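A1	agene1
A1	agene2
A1	agene3
A1	agene4
A1	agene5
A2	agene1
A2	agene2
A2	agene3
A2	agene4
A2	agene5
A3	agene1
A3	agene2
A3	agene3
A3	agene4
A3	agene5
A4	agene1
A4	agene2
A4	agene3
A4	agene4
A4	agene5
A5	agene1
A5	agene2
A5	agene3
A5	agene4
A5	agene5
B1	bgene1
B1	bgene2
B1	bgene3
B1	bgene4
B1	bgene5
B2	bgene1
B2	bgene2
B2	bgene3
B2	bgene4
B2	bgene5
B3	bgene1
B3	bgene2
B3	bgene3
B3	bgene4
B3	bgene5
B4	bgene1
B4	bgene2
B4	bgene3
B4	bgene4
B4	bgene5
B5	bgene1
B5	bgene2
B5	bgene3
B5	bgene4
B5	bgene5
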