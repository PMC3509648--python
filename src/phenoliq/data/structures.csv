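compound,smiles,provenance
Gallic acid,OC(=O)c1cc(O)c(O)c(O)c1,curated
Gentisic acid,OC(=O)c1cc(O)ccc1O,curated
Protocatechuic acid,OC(=O)c1ccc(O)c(O)c1,curated
Salicylic acid,OC(=O)c1ccccc1O,curated
Syringic acid,COc1cc(C(O)=O)cc(OC)c1O,curated
Vanillic acid,COc1cc(C(O)=O)ccc1O,curated
"2,4-Dihydroxybenzoic acid",OC(=O)c1ccc(O)cc1O,curated
3-Methoxybenzoic acid,COc1cccc(C(O)=O)c1,curated
4-Hydroxybenzoic acid,OC(=O)c1ccc(O)cc1,curated
Caffeic acid,OC(=O)/C=C/c1ccc(O)c(O)c1,curated
Chlorogenic acid,O[C@@H]1C[C@](O)(C[C@H](OC(=O)/C=C/c2ccc(O)c(O)c2)[C@@H]1O)C(O)=O,curated
Ferulic acid,COc1cc(/C=C/C(O)=O)ccc1O,curated
m-Coumaric acid,OC(=O)/C=C/c1cccc(O)c1,curated
o-Coumaric acid,OC(=O)/C=C/c1ccccc1O,curated
p-Coumaric acid,OC(=O)/C=C/c1ccc(O)cc1,curated
Sinapic acid,COc1cc(/C=C/C(O)=O)cc(OC)c1O,curated
trans-Cinnamic acid,OC(=O)/C=C/c1ccccc1,curated
Dihydrocaffeic acid,OC(=O)CCc1ccc(O)c(O)c1,curated
Homovanillic acid,COc1cc(CC(O)=O)ccc1O,curated
DOPAC,OC(=O)Cc1ccc(O)c(O)c1,curated
4-Hydroxyphenylacetic acid,OC(=O)Cc1ccc(O)cc1,curated
Ellagic acid,O=c1oc2c(O)c(O)cc3c(=O)oc4c(O)c(O)cc1c4c23,curated
Vanillin,COc1cc(C=O)ccc1O,curated
Tyrosol,OCCc1ccc(O)cc1,curated
Apigenin,Oc1ccc(-c2cc(=O)c3c(O)cc(O)cc3o2)cc1,curated
Chrysin,Oc1cc(O)c2c(c1)oc(-c1ccccc1)cc2=O,curated
Luteolin,Oc1cc(O)c2c(c1)oc(-c1ccc(O)c(O)c1)cc2=O,curated
Luteolin-7-O-glucoside,OC[C@H]1O[C@@H](Oc2cc(O)c3c(c2)oc(-c2ccc(O)c(O)c2)cc3=O)[C@H](O)[C@@H](O)[C@@H]1O,curated
Kaempferide,COc1ccc(-c2oc3cc(O)cc(O)c3c(=O)c2O)cc1,curated
Myricetin,Oc1cc(O)c2c(c1)oc(-c1cc(O)c(O)c(O)c1)c(O)c2=O,curated
Quercetin,Oc1cc(O)c2c(c1)oc(-c1ccc(O)c(O)c1)c(O)c2=O,curated
Rutin,C[C@@H]1O[C@@H](OC[C@H]2O[C@@H](Oc3c(-c4ccc(O)c(O)c4)oc4cc(O)cc(O)c4c3=O)[C@H](O)[C@@H](O)[C@@H]2O)[C@H](O)[C@H](O)[C@H]1O,curated
Hesperidin,C[C@@H]1O[C@@H](OC[C@H]2O[C@@H](Oc3cc(O)c4c(c3)O[C@@H](c3ccc(OC)c(O)c3)CC4=O)[C@H](O)[C@@H](O)[C@@H]2O)[C@H](O)[C@H](O)[C@H]1O,curated
Isosakuranetin,COc1ccc(cc1)[C@@H]1CC(=O)c2c(O)cc(O)cc2O1,curated
Naringenin,Oc1ccc(cc1)[C@@H]1CC(=O)c2c(O)cc(O)cc2O1,curated
(+)-Catechin,O[C@H]1Cc2c(O)cc(O)cc2O[C@@H]1c1ccc(O)c(O)c1,curated
(-)-Epicatechin,O[C@H]1Cc2c(O)cc(O)cc2O[C@H]1c1ccc(O)c(O)c1,curated
Genistein,Oc1ccc(-c2coc3cc(O)cc(O)c3c2=O)cc1,curated
(+)-Taxifolin,O[C@@H]1[C@H](Oc2cc(O)cc(O)c2C1=O)c1ccc(O)c(O)c1,curated
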