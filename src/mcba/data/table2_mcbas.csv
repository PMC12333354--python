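id,name,formula,mz_observed,ppm_printed,rt_min,fragments,collision_energy
11,leucolithocholic acid isomer 1,C30H51NO4,490.3911,3.88,4.35,341.2839;323.2737;132.1012;*86.0957,30
12,L-leucolithocholic acid,C30H51NO4,490.3906,2.73,5.01,341.2841;323.2735;132.1018;*86.0959,30
13,leucolithocholic acid isomer 2,C30H51NO4,490.3908,1.4,5.16,132.1010;*86.0956,30
14,5-aminovaloisolithocholic acid,C29H49NO4,476.3735,0.42,3.14,458.3624;341.2821;323.2722;118.0848;*100.0743,30
15,5-aminovalolithocholic acid,C29H49NO4,476.3751,2.76,3.75,458.3650;341.2831;323.2723;118.0819;*100.0714,30
16,valolithocholic acid isomer 1,C29H49NO4,476.3746,2.45,3.95,341.2798;323.2690;118.0831;*72.0776,30
17,L-valolithocholic acid,C29H49NO4,476.3735,0.03,4.6,458.3624;341.2836;323.2734;118.0862;*72.0704,30
18,valolithocholic acid isomer 2,C29H49NO4,476.3735,-2.05,4.77,118.0863;*72.0720,30
19,4-aminobutyric isolithocholic acid,C28H47NO4,462.3578,-1.7,3.0,104.0689;*86.0593,30
20,2-aminobutyric lithocholic acid isomer 1,C28H47NO4,462.3592,3.07,3.45,104.0652;*58.0599,30
21,4-aminobutyric lithocholic acid,C28H47NO4,462.3590,2.63,3.6,341.2837;323.2734;104.0700;*86.0594,30
22,2-aminobutyric lithocholic acid isomer 2,C28H47NO4,462.3567,-2.35,4.2,341.2844;323.2734;104.0700;*58.0638,30
23,2-aminobutyric lithocholic acid isomer 3,C28H47NO4,462.3583,1.12,4.3,104.0700;*58.0638,30
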