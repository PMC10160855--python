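underlying,congenital malformation,infection,IPRE,other,prematurity
congenital malformation,10,6,5,2,3
infection,1,61,4,1,26
IPRE,4,13,118,2,10
other,0,2,2,7,0
prematurity,0,6,10,3,44
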