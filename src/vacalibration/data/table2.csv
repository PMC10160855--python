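algorithm,quantity,n,congenital malformation,infection,IPRE,other,prematurity
insilicova,score,818,1.6,363.8,221.6,33.5,197.5
insilicova,pct,818,0.2,44.5,27.1,4.1,24.1
eava,score,818,29.1,479.5,144.3,32.7,132.3
eava,pct,818,3.6,58.6,17.6,4.0,16.2
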