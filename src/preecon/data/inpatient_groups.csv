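label,n,los_median_days,los_mean_days,cost_median_eur,cost_mean_eur
suspected_no_birth,36,3.0,4.5,5225,6300
vaginal_with_pe,101,4.0,5.4,8321,10715
csection_with_pe,164,6.0,7.8,14010,17094
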