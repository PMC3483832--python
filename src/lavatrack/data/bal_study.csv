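subject,v_total_ml,v_retrieved_ml,tvc1_ml
1,300,153,125.48
2,300,140,107.80
3,300,190,106.16
4,300,149,130.00
5,300,150,123.37
6,300,232,42.03
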