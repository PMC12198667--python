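# Repeated-dose oral toxicity NOAEL/LOAELs for DEHP from the public ECHA
# registration databases (<100-day in vivo studies including females).
# Sex-specific values are separate rows sharing a dataset_id; ranges
# ("50 to 80", "3-28 d") are stored at their lower bound / as text.
dataset_id,species,duration_days,value,value_type,sex
4,Mouse,90,100,NOAEL,
7,Rat,14,2000,LOAEL,
11,Rat,16,42,NOAEL,
17,Rat,14,50,NOAEL,
20,Rat,21,11,LOAEL,male
20,Rat,21,12,LOAEL,female
22,Rat,90,3.7,NOAEL,male
22,Rat,90,4.2,NOAEL,female
25,Rat,14,1500,NOAEL,
28,Rat,3-28,50,LOAEL,
30,Monkey,14,2000,LOAEL,
31,Rat,7-21,2500,LOAEL,
32_rsf_13_echa,Rat,90,320,NOAEL,
33,Rat,28,50,LOAEL,
44,Rat,90,63,LOAEL,male
44,Rat,90,73,LOAEL,female
57,Rat,3,50,NOAEL,
63,Monkey,91,500,NOAEL,
67,Rat,7-21,80,LOAEL,
key3_echa,Rat,90,3.7,NOAEL,
key1_rsf_key4_echa,Monkey,91,500,NOAEL,
7_echa,Mouse,91,100,NOAEL,
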