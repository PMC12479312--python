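HLA-A,HLA-B,HLA-C,count
A*03:01:01,B*07:02:01,C*07:02:01,15
A*02:01:01,B*13:02:01,C*06:02:01,10
A*01:01:01,B*08:01:01,C*07:01:01,6
A*02:01:01,B*07:02:01,C*07:02:01,4
A*02:01:01,B*40:01:01,C*03:04:01,3
A*02:01:01,B*57:01:01,C*06:02:01,2
A*03:01:01,B*56:01:01,C*01:02:01,2
A*25:01:01,B*18:01:01,C*12:03:01,2
A*02:01:01,B*15:01:01,C*03:04:01,1
A*02:01:01,B*27:05:02,C*02:02:02,1
A*25:01:01,B*35:01:01,C*04:01:01,1
A*26:01:01,B*38:01:01,C*12:03:01,1
A*31:01:02,B*51:01:01,C*05:01:01,1
A*68:01:01,B*40:01:01,C*03:04:01,1
A*68:01:02,B*44:02:01,C*07:04:01,1
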