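study_id,group_label,cohort_id,n,age_years,tiv_mean_cm3,tiv_sd_cm3,gmv_mean_cm3,gmv_sd_cm3,wmv_mean_cm3,wmv_sd_cm3,ga_weeks,bw_grams,male_pct,country,segmentation_method
Pascoe2019,,NZ_VLBW_1986,150,28.5,1504,140,669,61,513,61,28.8,1077,41.3,New Zealand,CAT12 toolbox (SPM12)
Lemola2017,,CH_1998_2006,57,10.0,1397,148,777,70,464,67,29.7,1447,65.3,Switzerland,New segment toolbox (SPM8)
Meng2016,,DE_BLS_1985,85,26.5,1385,,609.4,,554,,30.67,1356,55.3,Germany,VBM8 toolbox (SPM8)
Northam2011,positive cUS,UK_1989_1994,27,16,1601,222,757,57,418,46,27.1,1081,44.4,United Kingdom,VBM5 toolbox (SPM5)
Northam2011,normal cUS,UK_1989_1994,22,16.3,1480,193,765,65,438,49,28.1,1098,31.8,United Kingdom,VBM5 toolbox (SPM5)
Padilla2011,IUGR,ES_2006_2007,18,1.1,969.6,101.8,683.7,64.5,243.5,36.9,32.1,1060,38.9,Spain,VBM5 toolbox (SPM5)
Padilla2011,AGA,ES_2006_2007,15,1.1,1001.1,95.4,714.0,57.0,240.7,38.0,31,1580,73.3,Spain,VBM5 toolbox (SPM5)
SoriaPastor2009,,ES_1996_1998,20,9.3,1641.2,172.6,821.7,84.9,419.2,53.8,32.5,1754,55,Spain,SPM5
Narberhaus2007,GA <= 27,ES_BCN_1982_1994,9,14.1,1354.8,174.1,733.4,54.7,312.1,57.9,26.4,899,77.8,Spain,SPM2
Narberhaus2007,GA 28-30,ES_BCN_1982_1994,19,14.6,1488.5,164.9,771.3,133.2,377.2,57.9,29,1140,42.1,Spain,SPM2
Narberhaus2007,GA 31-33,ES_BCN_1982_1994,25,13.8,1445.3,146.4,778.1,72.1,372.0,52.1,31.7,1534,44,Spain,SPM2
Narberhaus2007,GA 34-36,ES_BCN_1982_1994,11,13.55,1473.3,148.4,780.3,69.9,389.8,45.1,34.6,2446,63.6,Spain,SPM2
Gimenez2006b,,ES_BCN_1982_1994,50,14.5,1488.8,148.8,787.8,80.8,377.2,47.4,29.9,1327,48,Spain,SPM2
Gimenez2006a,,ES_BCN_1982_1994,30,14.3,1460,140,780,70,360,50,29.1,1108,,Spain,SPM2
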