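time_h,concentration_mg_per_ml
0,0
1,0.0715
2,0.0855
3,0.0780
4,0.0735
5,0.0490
6,0.0535
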