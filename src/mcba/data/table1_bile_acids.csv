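id,name,abbreviation,formula,mz_observed,ppm_printed,rt_min,fragments,collision_energy
1,chenodeoxycholic acid,CDCA,C24H40O4,391.2859,1.32,3.4,391.2862;373.2750,40
2,lithocholic acid,LCA,C24H40O3,375.2922,4.6,5.18,375.2939;357.2838;355.2669,50
3,7-oxo-lithocholic acid,7-oxoLCA,C24H38O4,389.2712,3.76,2.8,389.2722;345.2808;343.2657,40
4,3-oxo-5b-cholan-24-oic acid,3-oxoLCA,C24H38O3,373.2751,0.75,5.35,373.2737;355.2634,30
5,ursodeoxycholic acid,UDCA,C24H40O4,391.2851,-0.72,2.37,391.2859;373.2780,40
6,isolithocholic acid,isoLCA,C24H40O3,375.2916,3.01,4.5,375.2920;357.2808;355.2650,50
7,isoursodeoxycholic acid,isoUDCA,C24H40O4,391.2849,-1.23,2.2,391.2855;373.2784,40
8,3-oxo-chenodeoxycholic acid,3-oxoCDCA,C24H38O4,389.2711,3.5,3.68,389.2708;345.2813;343.2664;371.2643,40
9,7-oxo-5b-cholan-24-oic acid,7-oxoChol,C24H38O3,373.2759,2.89,4.69,373.2740;355.2638,30
10,isochenodeoxycholic acid,isoCDCA,C24H40O4,391.2850,-0.98,2.73,391.2858;373.2755,40
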