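subject,group,interior_pct,superficial_pct,deep_pct
BMP1,BMP,49,5,58
BMP2,BMP,79,81,76
BMP3,BMP,68,59,66
Di1,DIPY,13,0,1
Di2,DIPY,31,20,42
Di3,DIPY,74,13,42
NS1,NS,9,0,2
NS2,NS,17,8,13
NS3,NS,55,3,59
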