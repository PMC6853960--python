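agene1	agene2
agene2	agene3
agene3	agene4
agene4	agene5
agene5	agene1
bgene1	bgene2
bgene2	bgene3
bgene3	bgene4
bgene4	bgene5
bgene5	bgene1
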