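molecule,target,energy
3-Epikatonic Acid,PPARG,-2.3
Hederagenin,PPARG,-0.6
Triptonide,PPARG,-6.5
Triptotriterpenic Acid B,PPARG,4.4
Triptotriterpenic Acid C,PPARG,-3.1
Ursolic Acid,PPARG,-2.8
3-Epikatonic Acid,PTGS2,-8.7
Hederagenin,PTGS2,-8.8
Triptonide,PTGS2,-8.5
Triptotriterpenic Acid B,PTGS2,-8.5
Triptotriterpenic Acid C,PTGS2,-8.6
Ursolic Acid,PTGS2,-8.5
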