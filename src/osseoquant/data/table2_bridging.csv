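subject,group,timepoint,value
NS1,NS,2,55
NS1,NS,4,73
NS1,NS,6,74
NS1,NS,8,73
NS1,NS,10,76
NS1,NS,12,79
NS1,NS,microct,0
NS2,NS,2,54
NS2,NS,4,94
NS2,NS,6,96
NS2,NS,8,98
NS2,NS,10,97
NS2,NS,12,100
NS2,NS,microct,5
NS3,NS,2,86
NS3,NS,4,95
NS3,NS,6,100
NS3,NS,8,100
NS3,NS,10,100
NS3,NS,12,100
NS3,NS,microct,24
BMP1,BMP,4,100
BMP1,BMP,6,100
BMP1,BMP,8,100
BMP1,BMP,10,100
BMP1,BMP,12,100
BMP1,BMP,microct,100
BMP2,BMP,2,100
BMP2,BMP,4,100
BMP2,BMP,6,100
BMP2,BMP,8,100
BMP2,BMP,10,100
BMP2,BMP,12,100
BMP2,BMP,microct,90
BMP3,BMP,2,100
BMP3,BMP,4,100
BMP3,BMP,6,100
BMP3,BMP,8,100
BMP3,BMP,10,100
BMP3,BMP,12,100
BMP3,BMP,microct,81
Dipy1,DIPY,2,85
Dipy1,DIPY,4,93
Dipy1,DIPY,6,95
Dipy1,DIPY,8,98
Dipy1,DIPY,10,98
Dipy1,DIPY,12,98
Dipy1,DIPY,microct,2
Dipy2,DIPY,2,68
Dipy2,DIPY,4,69
Dipy2,DIPY,8,79
Dipy2,DIPY,10,81
Dipy2,DIPY,12,86
Dipy2,DIPY,microct,4
Dipy3,DIPY,2,79
Dipy3,DIPY,4,83
Dipy3,DIPY,6,92
Dipy3,DIPY,8,91
Dipy3,DIPY,10,93
Dipy3,DIPY,12,93
Dipy3,DIPY,microct,22
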