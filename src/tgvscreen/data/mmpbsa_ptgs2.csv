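system,evdw_mean,evdw_std,eele_mean,eele_std,gsolv_mean,gsolv_std,ggas_mean,ggas_std,gtotal_mean,gtotal_std
3-Epikatonic Acid,-46.81,3.47,-9.16,6.00,30.95,5.37,-55.97,6.81,-25.03,4.00
Hederagenin,-43.96,3.74,2.78,11.80,13.51,10.54,-41.18,11.19,-27.67,4.45
Triptonide,-25.70,4.91,-5.77,5.35,17.40,7.44,-31.46,8.27,-14.06,2.46
Triptotriterpenic Acid B,-46.53,2.86,-7.10,5.04,25.90,5.52,-53.62,6.03,-27.72,3.04
Triptotriterpenic Acid C,-46.62,3.49,-17.23,4.84,37.68,3.69,-63.86,5.72,-26.18,5.57
Ursolic Acid,-48.58,4.19,-4.13,6.36,25.52,8.20,-52.71,9.37,-27.19,3.28
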