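analyte_id,name,category,mz_neg,mz_pos,hilic_neg_time,hilic_neg_flag,ce_alkaline_time,ce_alkaline_flag,ce_acidic_time,ce_acidic_flag,hilic_pos_time,hilic_pos_flag,ce_cation_time,ce_cation_flag
1,L-serine,amino_acid,104.0348,106.0504,10.8,detected,7.7,comigrating,,absent,10.8,detected,19.5,detected
2,L-proline,amino_acid,114.0555,116.0712,11.6,detected,7.8,comigrating,,absent,11.8,detected,21.5,detected
3,L-valine,amino_acid,116.0712,118.0869,10.1,detected,7.8,comigrating,,absent,10.1,detected,19.6,detected
4,L-threonine,amino_acid,118.0504,120.0661,10.6,detected,7.8,comigrating,,absent,10.6,detected,20.8,detected
5,L-cysteine,amino_acid,120.0119,122.0276,,absent,7.8,comigrating,,absent,13.2,detected,22.3,failed
6,L-leucine,amino_acid,130.0869,132.1025,9.1,detected,7.8,comigrating,,absent,9.1,detected,20.1,detected
7,L-isoleucine,amino_acid,130.0869,132.1025,9.4,detected,7.8,comigrating,,absent,9.4,detected,20.4,detected
8,L-aspartic acid,amino_acid,132.0297,134.0454,9.9,detected,15.9,detected,38.6,failed,10.0,detected,23.4,detected
9,L-lysine,amino_acid,145.0978,147.1134,,absent,5.4,detected,,absent,15.5,failed,12.7,detected
10,L-glutamic acid,amino_acid,146.0454,148.0610,10.2,detected,14.5,detected,,absent,10.2,detected,22.0,detected
11,L-methionine,amino_acid,148.0433,150.0589,9.3,detected,7.8,comigrating,,absent,9.3,detected,21.3,detected
12,L-histidine,amino_acid,154.0617,156.0773,,absent,7.4,detected,,absent,,absent,13.6,detected
13,L-phenylalanine,amino_acid,164.0712,166.0869,8.7,detected,7.8,comigrating,,absent,8.6,detected,22.2,detected
14,L-arginine,amino_acid,173.1039,175.1196,,absent,5.5,detected,,absent,,absent,13.3,detected
15,L-tyrosine,amino_acid,180.0661,182.0818,8.8,detected,7.8,comigrating,,absent,8.8,detected,23.2,detected
16,L-tryptophan,amino_acid,203.0821,205.0978,8.1,detected,7.8,comigrating,,absent,8.1,detected,22.3,detected
17,benzenesulfinic acid,internal_std,141.0010,143.0167,3.5,failed,,absent,12.8,failed,,absent,,absent
18,2-nitrobenzoic acid,internal_std,166.0140,168.0297,3.1,detected,16.3,detected,19.2,detected,,absent,,absent
19,methionine sulfone,internal_std,180.0331,182.0487,9.8,detected,7.7,comigrating,,absent,9.9,detected,24.6,detected
20,pentetic acid,internal_std,392.1306,394.1462,10.3,detected,30.7,failed,,absent,10.4,detected,,absent
21,succinate,metabolite,117.0188,119.0345,7.7,detected,,absent,37.7,detected,,absent,,absent
22,nicotinic acid,metabolite,122.0242,124.0399,6.3,detected,17.4,detected,19.2,detected,6.4,detected,20.0,detected
23,tartaric acid,metabolite,149.0086,151.0243,,absent,,absent,30.4,detected,,absent,,absent
24,citric acid,metabolite,191.0192,193.0348,,absent,,absent,32.1,failed,,absent,,absent
25,caffeine,metabolite,193.0726,195.0882,,absent,,absent,,absent,4.0,detected,,absent
26,ATP,metabolite,505.9879,508.0036,10.2,failed,25.3,failed,,absent,10.4,failed,,absent
27,NAD,metabolite,662.1013,664.1170,10.5,detected,10.1,detected,38.5,failed,10.6,detected,,absent
28,NADH,metabolite,664.1170,666.1327,8.6,detected,13.6,failed,,absent,8.7,detected,,absent
29,L-fucose,carbohydrate,163.0607,165.0763,,absent,7.8,comigrating,38.9,failed,,absent,,absent
30,D-mannose,carbohydrate,179.0556,181.0713,6.5,detected,7.8,comigrating,38.9,failed,,absent,,absent
31,alpha-D-glucose,carbohydrate,179.0556,181.0713,6.8,detected,7.8,comigrating,38.9,failed,,absent,,absent
32,alpha-D-galactose,carbohydrate,179.0556,181.0713,7.5,detected,7.8,comigrating,38.9,failed,,absent,,absent
33,D-mannose-1-phosphate,carbohydrate,259.0219,261.0376,10.3,detected,21.9,detected,15.9,detected,10.3,failed,,absent
34,beta-D-fructose-6-phosphate,carbohydrate,259.0219,261.0376,10.1,detected,19.4,detected,15.8,detected,10.1,failed,,absent
35,alpha-D-glucose-1-phosphate,carbohydrate,259.0219,261.0376,9.9,detected,19.0,detected,15.5,detected,9.9,failed,,absent
36,alpha-D-galactose-1-phosphate,carbohydrate,259.0219,261.0376,10.3,detected,18.1,detected,15.5,detected,10.3,detected,,absent
37,N-acetylneuraminate,carbohydrate,307.0909,309.1066,,absent,7.7,comigrating,,absent,,absent,,absent
38,UDP-glucose,carbohydrate,565.0472,567.0629,7.5,detected,14.7,detected,11.7,detected,7.6,detected,,absent
39,GDP-L-fucose,carbohydrate,588.0744,590.0901,8.7,detected,,absent,,absent,9.0,detected,,absent
40,CMP-N-acetylneuraminate,carbohydrate,613.1395,615.1552,9.0,detected,,absent,,absent,,absent,,absent
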