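time_h,amount_mg
0,0
1,1.262
2,1.403
3,1.280
4,1.222
5,0.803
6,0.878
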