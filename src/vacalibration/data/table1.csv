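algorithm,quantity,n,malaria,pneumonia,diarrhea,severe malnutrition,HIV,other,other infections
insilicova,score,1841,356.8,275.7,445.2,75.6,58.3,199.6,429.9
insilicova,pct,1841,19.4,15.0,24.2,4.1,3.2,10.8,23.3
eava,score,1841,144.2,437.1,344.4,148.3,116.1,106.6,544.2
eava,pct,1841,7.8,23.7,18.7,8.1,6.3,5.8,29.6
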