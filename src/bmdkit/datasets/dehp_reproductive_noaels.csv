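# Reproductive (fertility) toxicity NOAEL/LOAELs for DEHP from the public
# ECHA registration databases (<100-day in vivo studies including females).
# Ranges ("140-493", ">=95", "55 to 58") are stored at their lower bound.
dataset_id,species,duration_days,value,value_type,sex
3,Mouse,98,150,LOAEL,
20_rsf_7_echa,Mouse,17,95,NOAEL,
12,Mouse,2-30,140,NOAEL,
28_rsf_13_echa,Rat,10,1500,LOAEL,
15,Rat,90,3.7,NOAEL,
18,Rat,90,1060,NOAEL,
19,Mouse,7+98,14,NOAEL,
22,Monkey,91,2500,NOAEL,
26,Rat,90,320,NOAEL,
29_rsf_14_echa,Rat,1-12,2000,LOAEL,
31,Mouse,45,55,NOAEL,
35,Rat,22,4900,LOAEL,
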