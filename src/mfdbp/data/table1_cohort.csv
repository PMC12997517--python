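participant,abx_years,biopsy_year,mean_mfs_um2,cov_mfs,sd_mfs_um2,mfd_fibres_mm2,mfa_pct,fat_pct,cfa_pct,genotype
1,1.0,1983,457.9,0.58,265.7,1471.9,68.9,0.2,29.6,NA
2,1.9,1977,565.3,0.48,271.9,1227.0,72.3,0.1,26.7,NA
3,2.0,1975,622.1,0.53,328.7,1069.5,68.7,0.2,30.7,exon44-47 del
4,2.4,1979,598.1,0.56,336.2,1149.8,71.6,1.7,25.8,exon56 del
5,3.3,1977,851.2,0.54,455.7,656.8,57.3,0.7,39.2,negative
6,3.7,1975,531.3,0.44,230.9,953.5,53.7,0.2,45.7,exon44-47 del
7,4.0,1984,1037.9,0.53,551.2,563.2,53.5,1.3,41.6,negative
8,4.1,1979,577.5,1.20,693.4,867.2,53.4,5.3,40.3,exon44-51 del
9,4.3,1973,828.5,0.50,417.0,766.0,65.7,0.6,32.1,exon56 del
10,4.6,1984,870.4,0.65,568.3,545.5,45.9,1.7,48.9,exon44 del
11,4.7,1978,721.1,0.51,365.7,815.2,62.1,0.8,36.7,exon36 del
12,5.0,1980,1007.4,0.50,503.6,571.1,59.5,1.7,37.3,exon43-50 del
13,5.2,1980,624.3,0.53,330.3,976.4,64.9,0.1,34.0,negative
14,6.0,1975,725.1,0.82,591.6,552.0,38.5,1.4,58.7,negative
15,6.2,1977,1352.0,0.43,585.0,454.7,65.8,0.1,31.6,negative
16,6.2,1977,1176.2,1.11,1309.4,365.8,42.2,1.4,54.6,NA
17,6.2,1978,556.3,0.88,489.5,559.9,29.2,0.7,67.1,"exon20, exon59 Mut"
18,6.3,1979,1602.3,0.78,1244.7,300.7,51.7,3.5,44.4,NA
19,6.4,1979,1520.6,0.95,1442.2,343.8,54.7,3.1,40.7,NA
20,6.5,1979,1554.0,0.61,954.3,400.7,66.8,0.5,31.7,exon6-8 del
21,6.6,1983,1683.7,0.70,1176.0,216.6,36.3,1.5,59.9,negative
22,7.0,1978,850.3,0.73,623.7,553.8,47.1,3.9,45.3,negative
23,7.2,1979,680.0,0.71,479.3,572.7,39.8,13.2,46.6,exon46-48 del
24,7.2,1976,970.2,0.98,954.0,445.2,45.8,3.6,50.2,NA
25,7.8,1980,772.0,0.60,464.8,458.1,36.4,6.1,57.0,NA
26,8.3,1980,1231.8,1.72,2118.5,245.4,30.4,6.4,62.4,NA
27,8.7,1982,1048.4,1.26,1324.3,497.9,53.9,0.05,41.7,exon50 del
28,8.8,1981,1327.3,0.82,1081.8,282.9,38.6,3.5,55.0,exon3 del
29,8.9,1979,613.6,0.86,526.5,386.5,23.5,18.6,55.9,negative
30,9.1,1982,1285.4,0.95,1215.0,423.0,59.0,5.0,33.6,exon44 del
31,9.7,1976,889.0,0.75,666.2,291.0,25.4,3.2,68.2,negative
32,9.8,1982,1203.7,0.78,943.5,414.1,52.8,8.6,37.3,exon51-60 del
33,10.3,1980,3643.5,0.99,3603.9,143.9,58.2,10.3,30.8,exon12 dupl
34,10.7,1982,909.6,0.90,821.4,240.5,20.8,6.0,71.6,exon44 del
35,10.9,1977,1565.2,0.77,1199.8,393.5,67.7,3.0,28.7,exon56 del
36,12.8,1983,1028.5,1.07,1096.0,219.3,20.9,3.4,73.7,NA
37,15.1,1973,1953.9,0.92,1787.6,170.2,33.9,9.4,54.6,NA
38,16.3,1973,1504.0,1.46,2189.0,172.1,26.5,15.4,55.9,exon46-49 del
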