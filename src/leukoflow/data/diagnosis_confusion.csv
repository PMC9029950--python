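,AML,B-ALL,T-ALL,Normal,Abnormal
AML,134,0,0,0,4
B-ALL,0,52,0,0,1
T-ALL,0,0,7,0,2
Normal,0,0,0,94,0
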