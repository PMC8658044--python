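experiment,dataset,value
C1,CAPST,2e-06
C1,DUD-E,0.005
C1,GLL&GDD,0.014
C1,MUV,0.49
C1,NRLiSt_BDB,0.012
C1,ULS-UDS,0.115
C2,CAPST,0.013
C2,DUD-E,0.145
C2,GLL&GDD,0.333
C2,MUV,0.867
C2,NRLiSt_BDB,0.104
C2,ULS-UDS,0.5
C3,CAPST,0.004
C3,DUD-E,0.001
C3,GLL&GDD,0.003
C3,MUV,0.327
C3,NRLiSt_BDB,0.003
C3,ULS-UDS,0.011
C4,CAPST,0.017
C4,DUD-E,0.186
C4,GLL&GDD,0.206
C4,MUV,1.005
C4,NRLiSt_BDB,0.024
C4,ULS-UDS,0.607
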