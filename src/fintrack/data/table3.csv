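video,control,treated
1,1.6626,0.9027
2,1.8257,1.0455
3,2.0972,1.1478
4,2.1778,1.2754
5,2.3986,1.7030
6,2.5000,1.9220
7,2.5371,1.9970
8,2.6378,2.2628
9,3.0467,2.5263
10,3.2198,2.5601
11,3.2270,2.9128
12,3.6779,3.1247
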