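quantity,value
me_analyte_pct,99.67
me_analyte_sd,2.04
me_is_pct,102.24
me_is_sd,2.26
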