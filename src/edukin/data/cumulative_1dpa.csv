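# Published mean labeling-index series: cumulative EdU exposure starting at
# 1 day post-amputation (regenerating Alitta virens, posterior bud).
# Specimens fixed after 15 min, 5, 10, 24 and 48 h of exposure; values are
# time-point means (percent) with their standard errors.
time_h,li_percent,sem_percent
0.25,1.8,0.7
5,17,1.9
10,30.1,4.1
24,64.9,2.8
48,85.7,2.5
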