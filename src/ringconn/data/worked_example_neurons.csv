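id,name,cell_class,cluster,sensory_origin,side
sens_ph_01,pharyngeal sensory 1,sensory,,pharyngeal,left
sens_ph_02,pharyngeal sensory 2,sensory,,pharyngeal,right
int_munin2,Munin 2,interneuron,,,left
rpn_CRZ_01,CRZ-1,rpn,CRZ,,left
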