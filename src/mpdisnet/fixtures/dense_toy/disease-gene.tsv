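Da	ga
Da	gb
Da	gc
Db	ga
Db	gb
Db	gc
Dc	ga
Dc	gb
Dc	gc
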