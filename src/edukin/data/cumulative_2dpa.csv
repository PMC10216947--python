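# Published mean labeling-index series: cumulative EdU exposure starting at
# 2 days post-amputation (regenerating Alitta virens, posterior bud).
# Specimens fixed after 15 min, 10, 24 and 48 h of exposure; values are
# time-point means (percent) with their standard errors.
time_h,li_percent,sem_percent
0.25,22.3,1.9
10,51,3.1
24,61.4,8.4
48,90.6,2.56
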