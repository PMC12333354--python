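name,formula,amino_position,proteinogenic,reference_rt_shift
glycine,C2H5NO2,alpha,true,
valine,C5H11NO2,alpha,true,
leucine,C6H13NO2,alpha,true,
2-aminobutyric acid,C4H9NO2,alpha,false,
3-aminobutyric acid,C4H9NO2,other,false,
4-aminobutyric acid,C4H9NO2,terminal,false,
5-aminovaleric acid,C5H11NO2,terminal,false,
taurine,C2H7NO3S,none,false,
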