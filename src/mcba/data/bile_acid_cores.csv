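name,abbreviation,formula,n_hydroxyl,epimer_of,reference_rt
chenodeoxycholic acid,CDCA,C24H40O4,2,,3.4
lithocholic acid,LCA,C24H40O3,1,,5.18
7-oxo-lithocholic acid,7-oxoLCA,C24H38O4,1,,2.8
3-oxo-5b-cholan-24-oic acid,3-oxoLCA,C24H38O3,0,,5.35
ursodeoxycholic acid,UDCA,C24H40O4,2,,2.37
isolithocholic acid,isoLCA,C24H40O3,1,LCA,4.5
isoursodeoxycholic acid,isoUDCA,C24H40O4,2,UDCA,2.2
3-oxo-chenodeoxycholic acid,3-oxoCDCA,C24H38O4,1,,3.68
7-oxo-5b-cholan-24-oic acid,7-oxoChol,C24H38O3,0,,4.69
isochenodeoxycholic acid,isoCDCA,C24H40O4,2,CDCA,2.73
deoxycholic acid,DCA,C24H40O4,2,,4.86
cholic acid,CA,C24H40O5,3,,
hyodeoxycholic acid,HDCA,C24H40O4,2,,
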