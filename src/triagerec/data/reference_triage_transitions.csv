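pre,severe_undertriage,moderate_undertriage,mild_undertriage,optimal,mild_overtriage,moderate_overtriage,severe_overtriage
severe_undertriage,0,0,0,0,0,0,0
moderate_undertriage,0,0,1,5,0,0,0
mild_undertriage,0,1,15,24,2,1,0
optimal,0,2,10,189,16,5,0
mild_overtriage,0,0,1,17,10,2,0
moderate_overtriage,0,0,0,5,5,7,0
severe_overtriage,0,0,0,0,0,1,1
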