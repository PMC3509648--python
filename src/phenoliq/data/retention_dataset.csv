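sr,compound,rt_exp,pred_smlr,pred_ufs_smlr,pred_smlr_ann,pred_ufs_smlr_ann,split
1,Gallic acid,1.63,1.82,2.12,1.94,2.54,train
2,Gentisic acid,3.02,3.36,3.65,3.28,3.49,train
3,Protocatechuic acid,2.43,2.61,3.04,2.67,2.94,validation
4,Salicylic acid,3.96,3.93,4.23,3.89,4.04,test
5,Syringic acid,3.27,3.36,2.58,3.10,2.61,train
6,Vanillic acid,3.14,3.29,3.05,3.07,2.93,train
7,"2,4-Dihydroxybenzoic acid",3.26,2.67,3.13,2.76,3.05,validation
8,3-Methoxybenzoic acid,4.32,4.25,3.53,4.37,3.31,train
9,4-Hydroxybenzoic acid,2.94,2.88,3.60,2.90,3.45,train
10,Caffeic acid,3.24,2.69,3.31,2.74,3.08,test
11,Chlorogenic acid,3.07,3.26,3.13,3.16,2.78,train
12,Ferulic acid,3.80,3.84,4.11,3.84,3.89,validation
13,m-Coumaric acid,3.88,3.69,3.94,3.67,3.71,train
14,o-Coumaric acid,4.07,4.39,4.42,4.31,4.37,train
15,p-Coumaric acid,3.63,3.47,3.70,3.45,3.54,train
16,Sinapic acid,3.85,3.86,3.80,3.89,3.59,train
17,trans-Cinnamic acid,4.69,4.80,4.38,4.69,4.14,validation
18,Dihydrocaffeic acid,3.00,2.84,2.52,2.85,2.57,train
19,Homovanillic acid,3.22,3.29,3.08,3.14,3.00,test
20,DOPAC,2.34,2.11,2.27,2.19,2.59,train
21,4-Hydroxyphenylacetic acid,2.92,3.34,2.64,3.28,2.79,validation
22,Ellagic acid,3.80,3.90,3.65,4.07,3.27,train
23,Vanillin,3.49,3.52,3.18,3.45,3.05,train
24,Tyrosol,2.73,3.00,2.80,3.05,2.77,train
25,Apigenin,5.14,5.01,4.88,5.16,4.99,validation
26,Chrysin,5.92,6.18,5.78,5.77,5.62,test
27,Luteolin,4.76,4.33,4.82,4.45,4.90,validation
28,Luteolin-7-O-glucoside,3.81,4.10,4.32,4.10,4.24,train
29,Kaempferide,6.06,5.65,5.91,5.66,5.74,train
30,Myricetin,4.28,3.98,4.03,3.98,4.00,train
31,Quercetin,4.76,4.28,4.87,4.39,4.89,validation
32,Rutin,3.73,3.91,3.62,3.82,3.62,train
33,Hesperidin,3.94,3.71,4.23,3.73,4.26,train
34,Isosakuranetin,5.94,5.74,5.45,5.68,5.43,train
35,Naringenin,5.11,5.05,4.87,5.20,5.04,train
36,(+)-Catechin,2.99,3.91,4.07,3.89,3.63,validation
37,(-)-Epicatechin,3.26,3.66,3.67,3.63,3.28,test
38,Genistein,5.09,5.15,5.12,5.37,5.21,train
39,(+)-Taxifolin,3.85,3.57,4.02,3.51,3.78,train
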