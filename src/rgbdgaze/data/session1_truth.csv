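start,end
5:37,5:38
8:19,8:20
12:10,12:11
16:15,16:16
20:44,20:45
23:09,23:10
31:36,31:38
33:00,33:01
36:12,36:13
45:18,45:20
47:46,47:47
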