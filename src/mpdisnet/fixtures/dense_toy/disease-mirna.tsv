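Da	mx
Da	my
Db	mx
Db	my
Dc	mx
Dc	my
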