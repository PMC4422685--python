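gene,species,efficiency
beta-actin_Ch,C. hamatus,0.959
beta-actin_Dl,D. labrax,1.107
apeh-1_Ch,C. hamatus,1.102
apeh-1_Dl,D. labrax,1.104
apeh-2_Ch,C. hamatus,0.922
apeh-2_Dl,D. labrax,1.054
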