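system,evdw_mean,evdw_std,eele_mean,eele_std,gsolv_mean,gsolv_std,ggas_mean,ggas_std,gtotal_mean,gtotal_std
3-Epikatonic Acid,-52.94,3.81,-12.39,7.76,32.12,6.57,-65.34,7.98,-33.22,4.32
Hederagenin,-54.88,3.73,-32.45,18.59,47.21,12.81,-87.33,18.17,-40.12,7.75
Triptonide,-45.31,2.38,-10.15,3.80,35.10,4.49,-55.47,5.23,-20.36,3.49
Triptotriterpenic Acid B,-60.37,3.09,-11.69,3.98,36.82,4.77,-72.06,4.64,-35.24,4.03
Triptotriterpenic Acid C,-58.80,3.05,-16.75,4.77,38.59,4.12,-75.55,5.18,-36.96,5.30
Ursolic Acid,-60.23,2.79,-7.18,1.75,32.38,2.18,-67.41,3.09,-35.03,3.33
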