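subject,tvcr1_pct,tvcr2_pct,tvcr3_pct
1,14,12,5
2,15,4,1
3,15,3,0
4,22,13,0
5,14,8,1
6,5,3,2
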