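compound,species,receptor,ec50_pM
C803-GIP,human,GIPR,0.7
C803-GIP,human,GLP-1R,704000
C803-GIP,human,GCGR,999999
C803-GIP,NHP,GIPR,1.1
C803-GIP,NHP,GLP-1R,181000
C803-GIP,NHP,GCGR,999999
C803-GIP,rat,GIPR,12.7
C803-GIP,rat,GLP-1R,381000
C803-GIP,rat,GCGR,999999
Ga-C803-GIP,human,GIPR,0.8
Ga-C803-GIP,human,GLP-1R,35700
Ga-C803-GIP,human,GCGR,63500
Ga-C803-GIP,NHP,GIPR,0.7
Ga-C803-GIP,NHP,GLP-1R,31600
Ga-C803-GIP,NHP,GCGR,120000
Ga-C803-GIP,rat,GIPR,14.8
Ga-C803-GIP,rat,GLP-1R,45000
Ga-C803-GIP,rat,GCGR,692000
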