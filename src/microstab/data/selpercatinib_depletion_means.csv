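time_min,conc_ng_ml
0,626
2.5,586
7.5,527
15,418
20,353
30,264
40,238
50,227
60,218
70,197
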