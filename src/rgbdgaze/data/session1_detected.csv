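start,end
5:37,5:38
8:19,8:20
12:10,12:11
16:15,16:16
20:44,21:12
22:23,23:10
30:33,30:34
31:36,31:38
33:00,33:01
36:12,37:34
45:17,45:19
47:46,47:47
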