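site_id,site_name,mean_vdsi_2004_06,mean_vdsi_2010,mean_vdsi_2015,median_vdsi_2004_06,median_vdsi_2010,median_vdsi_2015,pct_imposex_2004_06,pct_imposex_2010,pct_imposex_2015,pct_sterile_2004_06,pct_sterile_2010,pct_sterile_2015,rpsi_2004_06,rpsi_2010,rpsi_2015,condition_index_2010,condition_index_2015,distance_km
1,Kat O,3.92,4.08,,4.0,4.0,,100,100,,0.0,24.0,,1.59,9.33,,16.6,,2.7
2,Pak Sha Chau,3.57,3.14,,4.0,3.0,,100,100,,0.0,0.0,,0.37,8.14,,18.7,,4.9
3,Chek Chau,3.50,3.10,,3.5,3.0,,100,100,,0.0,0.0,,0.57,4.74,,18.3,,10.3
4,Wu Kwai Sha,2.67,3.56,,3.0,3.5,,100,100,,0.0,22.2,,0.17,6.00,,24.4,,4.3
5,Heng On,3.64,,,4.0,,,100,,,0.0,,,0.84,,,,,18.5
6,Wong Mau Chau,3.03,3.09,,3.0,3.0,,100,100,,0.0,18.2,,0.11,4.17,,15.8,,17.0
7,Kong Tau Pai,2.38,2.69,,2.0,3.0,,100,100,,0.0,0.0,,0.06,6.36,,19.0,,11.4
8,Sai Kung Pier,4.70,4.94,4.78,4.0,5.0,5.0,100,100,100,40.0,72.2,55.6,34.38,94.66,48.00,20.5,20.3,0.2
9,UST,4.17,4.55,,4.0,4.0,,100,100,,11.1,45.0,,8.85,48.60,,21.6,,2.9
10,Clear Water Bay,3.04,2.81,4.71,3.0,2.0,5.0,100,100,100,0.0,9.5,52.9,0.53,1.71,31.70,19.3,22.4,8.9
11,Shek Mei Tao,3.22,3.33,,3.0,3.0,,100,100,,0.0,12.5,,0.15,3.32,,19.4,,5.8
12,Tung Lung Island,4.00,3.92,,4.0,4.0,,100,100,,0.0,16.0,,12.59,13.06,,18.9,,5.4
13,Waglan Island,3.00,2.61,,3.0,3.0,,100,100,,0.0,0.0,,0.18,1.19,,20.0,,11.5
14,Po Toi,3.52,2.76,3.61,4.0,3.0,3.0,100,100,100,0.0,5.9,13.0,2.32,2.19,9.61,18.6,18.6,11.9
15,Shek O,3.90,4.53,4.40,4.0,5.0,4.0,100,100,100,5.0,52.9,35.0,29.65,18.09,21.55,22.5,16.8,4.8
16,Turtle Cove,3.33,3.30,3.74,3.0,3.0,4.0,100,100,100,0.0,10.0,15.8,0.43,3.96,8.05,21.7,19.6,6.4
17,Chung Hum Kok,4.10,4.56,,4.0,4.5,,100,100,,4.8,50.0,,9.01,10.82,,25.1,,4.7
18,Repulse Bay,3.90,3.97,,4.0,4.0,,100,100,,10.5,26.7,,11.84,11.02,,24.8,,3.7
19,Deep Water Bay,4.35,3.45,4.90,4.0,3.0,5.0,100,100,100,29.4,25.0,57.1,7.72,7.10,33.12,15.2,21.9,2.5
20,Aberdeen,5.00,5.05,5.21,5.0,5.0,5.0,100,100,100,83.3,71.4,91.7,64.22,26.05,42.96,22.8,24.9,1.4
21,Sok Kwu Wan,5.36,5.73,5.22,6.0,6.0,5.0,100,100,100,71.4,93.3,94.4,12.07,37.70,38.87,23.8,24.5,0.4
22,Ha Mei Wan,3.65,4.41,,4.0,4.0,,100,100,,0.0,40.7,,1.89,16.72,,25.6,,2.9
23,Mui Wo,4.00,3.05,,4.0,3.0,,100,100,,0.0,5.3,,3.05,8.76,,29.0,,0.8
24,Cheung Sha,4.00,3.79,,4.0,3.0,,100,100,,0.0,26.3,,1.26,13.73,,16.8,,6.2
25,Tai O,3.79,4.17,,4.0,4.0,,100,100,,0.0,39.1,,3.18,24.80,,20.0,,0.2
26,Butterfly Beach,4.11,3.96,4.95,4.0,4.0,5.0,100,100,100,33.3,21.7,60.0,15.56,34.40,46.19,26.8,27.4,1.7
27,Kadoorie Beach,4.87,4.00,4.47,5.0,4.0,5.0,100,100,100,53.3,28.6,52.9,38.43,21.21,43.60,28.9,25.4,0.9
28,Pak Sha Wan,4.46,4.79,,,5.0,,100,100,,25.0,57.9,,60.61,46.58,,24.4,,0.0
29,Waterfall Bay,4.06,4.87,,,5.0,,100,100,,6.3,53.3,,59.80,11.56,,26.1,,1.5
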