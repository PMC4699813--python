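source,target,sign
SOCS1,JAK1,-1
SOCS3,JAK1,-1
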