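protein,region,start,end,n_negative,n_positive
APEH-1_Tb,N-ter,1,450,64,58
APEH-1_Tb,C-ter,461,728,29,26
APEH-2_Tb,N-ter,1,420,42,51
APEH-2_Tb,C-ter,431,690,24,31
APEH-1_Ch,N-ter,1,450,56,57
APEH-1_Ch,C-ter,461,729,29,27
APEH-2_Ch,N-ter,1,420,46,53
APEH-2_Ch,C-ter,431,690,24,31
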