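group,method,healthy,sub_healthy,poor,empty
A,actual,75,6,2,1
A,proposed,72,4,2,1
A,comparison,69,4,1,1
B,actual,94,6,3,2
B,proposed,87,3,1,1
B,comparison,82,4,2,1
C,actual,72,6,4,2
C,proposed,68,4,2,2
C,comparison,64,3,3,1
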