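subject,group,volume_mm3
NS1,NS,5793
NS2,NS,6289
NS3,NS,6961
BMP1,BMP,7514
BMP2,BMP,7586
BMP3,BMP,7763
Dipy1,DIPY,5936
Dipy2,DIPY,6325
Dipy3,DIPY,7137
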