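nominal_conc,level_name,mean_back_calc,sd,n
1,LLQC,0.95,0.02,6
3,LQC,3.09,0.03,6
15,,15.16,0.19,6
50,,50.98,1.10,6
100,,105.06,1.47,6
300,,303.45,2.36,6
500,,502.91,1.41,6
900,MQC,898.67,4.33,6
1500,,1492.58,11.37,6
2400,HQC,2387.68,34.32,6
3000,,3025.03,36.16,6
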