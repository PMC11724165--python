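fault_name,fissure_count,length_min_m,length_max_m
Maduo-Gande fault,35,16,300
Maqu-Duoqueshan fault,75,280,2200
Kamuka fault,12,50,760
Kunlun-Jiangcuo fault,451,35,800
Southern edge of Gande fault,80,2,650
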