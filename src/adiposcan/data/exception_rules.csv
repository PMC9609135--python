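sex,chest,abdomen,hips,arms_legs,outcome
male,C,D,D,C,Overweight
male,A,B,B,B,Normal
male,B,C,B,B,Normal
male,D,D,B~C,B~C,Overweight
male,A~B,C~D,A~B,A~B,Normal
female,B~C,D,D,D,Overweight
female,B,C~D,D,C~D,Overweight
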