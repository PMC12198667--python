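study_id,endpoint_id,ces,bmdl,bmd,bmdu,ratio_bmd_bmdl,ratio_bmdu_bmdl,accepted,lowest_nonzero_dose,modeled
oral10_I,pct_days_estrus,+0.10,0,230,1329,NA,NA,0,0.02,1
oral10_I,pct_days_metestrus_diestrus,-0.10,134,240,1582,1.8,11.8,1,0.02,1
oral10_I,serum_progesterone,+0.10,9.1,36.6,204,4.0,22.4,1,0.02,1
oral10_I,serum_estradiol,+0.10,0,85.4,318,NA,NA,0,0.02,1
oral10_I,total_follicles,-0.10,75.9,193,1227,2.5,16.2,1,0.02,1
oral10_I,primordial_follicles,-0.10,2.6,193,1499,74.0,576.7,0,0.02,1
oral10_I,primary_follicles,+0.10,19.5,31,172,1.6,8.8,1,0.02,1
oral10_I,preantral_follicles,-0.10,142,193,284,1.4,2.0,1,0.02,1
oral10_I,antral_follicles,-0.10,0,103,392,NA,NA,0,0.02,1
oral10_I,early_follicles,-0.10,51.7,177,992,3.4,19.2,1,0.02,1
oral10_I,late_follicles,-0.10,0,166,748,NA,NA,0,0.02,1
oral30,pct_days_estrus,+0.10,97.2,206,949,2.1,9.8,1,0.02,1
oral30,pct_days_metestrus_diestrus,-0.10,90.3,181,607,2.0,6.7,1,0.02,1
oral30,serum_progesterone,-0.10,26,108,797,4.1,30.6,1,0.02,1
oral30,serum_estradiol,-0.10,48,109,394,2.3,8.3,1,0.02,1
oral30,total_follicles,-0.10,0,198,1206,NA,NA,0,0.02,1
oral30,primordial_follicles,-0.10,0,178,1114,NA,NA,0,0.02,1
oral30,primary_follicles,+0.10,105,275,2754,2.6,26.3,1,0.02,1
oral30,preantral_follicles,-0.10,37.5,97,264,2.6,7.1,1,0.02,1
oral30,antral_follicles,-0.10,48.4,105,283,2.2,5.8,1,0.02,1
oral30,early_follicles,-0.10,176,211,364,1.2,2.1,1,0.02,1
oral30,late_follicles,-0.10,60.5,124,341,2.1,5.6,1,0.02,1
diet30,pct_days_estrus,+0.10,176,234,366,1.3,2.1,1,0.024,1
diet30,pct_days_metestrus_diestrus,-0.10,246,289,638,1.2,2.6,1,0.024,1
diet30,serum_progesterone,-0.10,0,44.2,314,NA,NA,0,0.024,1
diet30,serum_estradiol,-0.10,55.1,203,1118,3.7,20.3,1,0.024,1
diet30,total_follicles,+0.10,43.3,165,740,3.8,17.1,1,0.024,1
diet30,primordial_follicles,+0.10,23.2,128,742,5.5,32.0,1,0.024,1
diet30,primary_follicles,+0.10,50.8,221,1310,4.4,25.8,1,0.024,1
diet30,preantral_follicles,+0.10,42.2,161,681,3.8,16.1,1,0.024,1
diet30,antral_follicles,+0.10,0,37.8,239,NA,NA,0,0.024,1
diet30,early_follicles,+0.10,0,113,613,NA,NA,0,0.024,1
diet30,late_follicles,+0.10,39.5,132,490,3.3,12.4,1,0.024,1
oral10_II,final_body_weight,-0.05,0,241,191,NA,NA,0,0.02,1
oral10_II,body_weight_change,+0.05,191,352,3048,1.8,15.9,1,0.02,1
oral10_II,initial_weight,NDR,NA,NA,NA,NA,NA,0,0.02,0
oral10_II,ovary_weight_abs,+0.05,0,93,891,NA,NA,0,0.02,1
oral10_II,ovary_weight_rel,+0.05,0,88,778,NA,NA,0,0.02,1
oral10_II,uterus_weight_abs,-0.05,54.5,182,1238,3.3,22.7,1,0.02,1
oral10_II,uterus_weight_rel,-0.05,60.4,190,1418,3.2,23.5,1,0.02,1
oral10_II,liver_weight_abs,-0.05,183,218,420,1.2,2.3,1,0.02,1
oral10_II,liver_weight_rel,-0.05,188,225,463,1.2,2.5,1,0.02,1
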