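animal_id,group,C2,C3,C4,C5,C6,C7,C8,T1,T2,total
naive_1,naive,0,0,29,197,213,350,178,10,0,977
naive_2,naive,0,0,9,229,241,369,224,39,0,1111
naive_3,naive,0,0,58,157,187,237,185,8,0,832
naive_4,naive,0,0,18,117,99,178,94,25,0,531
naive_5,naive,0,0,2,31,94,111,118,15,0,371
sci_1,sci,0,0,11,77,69,14,89,0,0,260
sci_2,sci,0,0,38,209,110,82,133,14,0,586
sci_3,sci,0,0,25,178,114,42,76,49,0,484
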