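level_name,nominal_conc,scope,n,mean,sd
LLQC,1,intra_batch,12,0.95,0.02
LQC,3,intra_batch,12,3.09,0.03
MQC,900,intra_batch,12,898.67,4.33
HQC,2400,intra_batch,12,2387.68,34.32
LLQC,1,inter_batch,18,0.93,0.02
LQC,3,inter_batch,18,3.16,0.10
MQC,900,inter_batch,18,912.08,15.59
HQC,2400,inter_batch,18,2375.59,24.66
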