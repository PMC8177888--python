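pre,post,count
sens_ph_01,int_munin2,2000
sens_ph_02,int_munin2,1233
int_munin2,rpn_CRZ_01,5652
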