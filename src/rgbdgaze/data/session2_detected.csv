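start,end
2:17,2:18
5:47,6:26
7:32,7:39
11:08,11:50
15:42,16:08
18:20,18:29
20:05,20:06
22:20,23:02
24:20,24:21
26:06,26:07
31:10,31:17
35:34,35:35
40:04,41:06
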