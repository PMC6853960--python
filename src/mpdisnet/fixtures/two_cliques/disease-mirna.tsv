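A1	amir1
A1	amir2
A1	amir3
A1	amir4
A2	amir1
A2	amir2
A2	amir3
A2	amir4
A3	amir1
A3	amir2
A3	amir3
A3	amir4
A4	amir1
A4	amir2
A4	amir3
A4	amir4
A5	amir1
A5	amir2
A5	amir3
A5	amir4
B1	bmir1
B1	bmir2
B1	bmir3
B1	bmir4
B2	bmir1
B2	bmir2
B2	bmir3
B2	bmir4
B3	bmir1
B3	bmir2
B3	bmir3
B3	bmir4
B4	bmir1
B4	bmir2
B4	bmir3
B4	bmir4
B5	bmir1
B5	bmir2
B5	bmir3
B5	bmir4
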