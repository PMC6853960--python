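amir1	agene1
amir1	agene2
amir1	agene3
amir1	agene4
amir1	agene5
amir2	agene1
amir2	agene2
amir2	agene3
amir2	agene4
amir2	agene5
amir3	agene1
amir3	agene2
amir3	agene3
amir3	agene4
amir3	agene5
amir4	agene1
amir4	agene2
amir4	agene3
amir4	agene4
amir4	agene5
bmir1	bgene1
bmir1	bgene2
bmir1	bgene3
bmir1	bgene4
bmir1	bgene5
bmir2	bgene1
bmir2	bgene2
bmir2	bgene3
bmir2	bgene4
bmir2	bgene5
bmir3	bgene1
bmir3	bgene2
bmir3	bgene3
bmir3	bgene4
bmir3	bgene5
bmir4	bgene1
bmir4	bgene2
bmir4	bgene3
bmir4	bgene4
bmir4	bgene5
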