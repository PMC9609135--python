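sample_id,dexa_class,bmi_class,whtr_class,whr_class,proposal_class
Sample 1,D,D,D,C,D
Sample 2,C,B,C,C,C
Sample 3,B,B,B,B,B
Sample 4,C,B,C,C,C
Sample 5,C,B,C,B,C
Sample 6,B,A,A,B,B
Sample 7,D,C,C,C,C
Sample 8,A,A,B,B,A
Sample 9,A,A,A,A,B
Sample 10,B,B,B,B,B
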