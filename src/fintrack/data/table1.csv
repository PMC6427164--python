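dish,group,total,hatched,hatchability_pct,mean_days_to_hatch
1,treated,15,15,100,16.8
2,treated,15,14,93.3,12.7
3,treated,15,15,100,12.7
4,treated,15,14,93.3,17.1
5,treated,15,14,100,15.7
6,control,15,15,100,13.7
7,control,15,15,100,16
8,control,15,13,86.7,14.6
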