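variant,sex,age_lo,age_hi,a_weight,b_height,c_const,unit
weight_only,male,18,30,0.0669,0,2.28,MJ_per_day
weight_only,male,30,60,0.0592,0,2.48,MJ_per_day
weight_only,male,60,110,0.0563,0,2.15,MJ_per_day
weight_only,female,18,30,0.0546,0,2.33,MJ_per_day
weight_only,female,30,60,0.0407,0,2.90,MJ_per_day
weight_only,female,60,110,0.0424,0,2.38,MJ_per_day
weight_height,male,18,30,0.0600,1.31,0.473,MJ_per_day
weight_height,male,30,60,0.0476,2.26,-0.574,MJ_per_day
weight_height,male,60,110,0.0478,2.26,-1.070,MJ_per_day
weight_height,female,18,30,0.0433,2.57,-1.180,MJ_per_day
weight_height,female,30,60,0.0342,2.10,-0.0486,MJ_per_day
weight_height,female,60,110,0.0356,1.76,0.0448,MJ_per_day
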