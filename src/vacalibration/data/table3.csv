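underlying,malaria,pneumonia,diarrhea,severe malnutrition,HIV,other,other infections
malaria,34,8,0,0,0,5,4
pneumonia,0,27,1,0,0,4,14
diarrhea,0,9,15,0,0,0,4
severe malnutrition,9,18,6,0,0,2,35
HIV,6,17,4,0,1,1,18
other,3,33,0,1,0,39,54
other infections,0,9,0,0,0,12,33
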