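family	enzyme_class
GH5	endoglucanase
GH7	endoglucanase
GH12	endoglucanase
GH45	endoglucanase
GH6	cellobiohydrolase
GH7	cellobiohydrolase
AA9	lpmo_cellulose
AA3_1	cdh
AA7	oligosaccharide_oxidase
AA13	lpmo_starch
GH10	xylanase
GH11	xylanase
AA14	lpmo_xylan
GH43	endoarabinanase
GH51	arabinofuranosidase
GH62	arabinofuranosidase
GH5	endomannanase
GH26	endomannanase
GH1	beta_glucosidase
GH2	mannosidase
GH3	xylosidase
AA12	pdh
GH28	polygalacturonase
GH78	rhamnosidase
PL1	pectin_lyase
PL3	pectin_lyase
PL4	pectin_lyase
PL20	pectin_lyase
CE8	pectin_methylesterase
AA1	laccase
AA2	peroxidase
AA3_2	oxidoreductase
AA3_3	oxidoreductase
AA3_4	oxidoreductase
AA4	vanillyl_alcohol_oxidase
AA5_1	glyoxal_oxidase
AA6	benzoquinone_reductase
CE10	noncarbohydrate_esterase
CE1	feruloyl_esterase
CE2	acetyl_esterase
CE3	acetyl_esterase
CE4	acetyl_esterase
CE5	acetyl_esterase
CE12	acetyl_esterase
CE16	acetyl_esterase
CE15	glucuronoyl_esterase
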