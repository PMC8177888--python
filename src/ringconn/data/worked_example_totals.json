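{"int_munin2": 10000, "rpn_CRZ_01": 10000}
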