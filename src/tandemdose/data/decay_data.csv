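# Radionuclide decay data compiled from evaluated nuclear data (NNDC/ENSDF and
# ICRP-107-style compilations). One row per decay branch or per emission.
# Conventions:
#   - beta_mean rows carry the MEAN beta energy of the branch, not the endpoint.
#   - yield is emissions per disintegration of the row's nuclide.
#   - decay rows have daughter/branching filled and emission fields empty;
#     emission rows have emission/energy_mev/yield filled and daughter empty.
#   - a nuclide row with no half-life is stable (terminal).
# Lines below 1% yield are retained so that yield-cutoff behaviour is exercised.
nuclide,half_life,half_life_unit,daughter,branching,emission,energy_mev,yield,source
Lu-177,6.6443,d,Hf-177,1.0,,,,ENSDF
Lu-177,6.6443,d,,,beta_mean,0.0477,0.1160,ENSDF
Lu-177,6.6443,d,,,beta_mean,0.1116,0.0900,ENSDF
Lu-177,6.6443,d,,,beta_mean,0.1491,0.7940,ENSDF
Lu-177,6.6443,d,,,gamma,0.20837,0.1041,ENSDF
Lu-177,6.6443,d,,,gamma,0.11295,0.0620,ENSDF
Lu-177,6.6443,d,,,gamma,0.32132,0.0022,ENSDF
Lu-177,6.6443,d,,,xray,0.06324,0.0287,ENSDF
Lu-177,6.6443,d,,,xray,0.06200,0.0168,ENSDF
Lu-177,6.6443,d,,,conversion_electron,0.04760,0.0390,ENSDF
Lu-177,6.6443,d,,,conversion_electron,0.10230,0.0105,ENSDF
Lu-177,6.6443,d,,,conversion_electron,0.14300,0.0075,ENSDF
Lu-177,6.6443,d,,,auger,0.00680,0.0110,ENSDF
Hf-177,,,,,,,,ENSDF
Ac-225,9.9203,d,Fr-221,1.0,,,,ENSDF
Ac-225,9.9203,d,,,alpha,5.8300,0.5070,ENSDF
Ac-225,9.9203,d,,,alpha,5.7925,0.1810,ENSDF
Ac-225,9.9203,d,,,alpha,5.7906,0.0860,ENSDF
Ac-225,9.9203,d,,,alpha,5.7322,0.0800,ENSDF
Ac-225,9.9203,d,,,alpha,5.7220,0.0290,ENSDF
Ac-225,9.9203,d,,,alpha,5.6824,0.0130,ENSDF
Ac-225,9.9203,d,,,alpha,5.6371,0.0440,ENSDF
Ac-225,9.9203,d,,,alpha,5.6080,0.0120,ENSDF
Ac-225,9.9203,d,,,alpha,5.2860,0.0040,ENSDF
Ac-225,9.9203,d,,,gamma,0.09980,0.0101,ENSDF
Ac-225,9.9203,d,,,gamma,0.15009,0.0055,ENSDF
Fr-221,4.801,min,At-217,1.0,,,,ENSDF
Fr-221,4.801,min,,,alpha,6.3410,0.8340,ENSDF
Fr-221,4.801,min,,,alpha,6.1264,0.1510,ENSDF
Fr-221,4.801,min,,,alpha,6.2430,0.0134,ENSDF
Fr-221,4.801,min,,,gamma,0.21810,0.1144,ENSDF
At-217,0.0326,s,Bi-213,1.0,,,,ENSDF
At-217,0.0326,s,,,alpha,7.0669,0.9989,ENSDF
Bi-213,45.61,min,Po-213,0.9784,,,,ENSDF
Bi-213,45.61,min,Tl-209,0.0216,,,,ENSDF
Bi-213,45.61,min,,,beta_mean,0.4920,0.6440,ENSDF
Bi-213,45.61,min,,,beta_mean,0.3200,0.3020,ENSDF
Bi-213,45.61,min,,,alpha,5.8750,0.0194,ENSDF
Bi-213,45.61,min,,,alpha,5.5490,0.0016,ENSDF
Bi-213,45.61,min,,,gamma,0.44045,0.2590,ENSDF
Po-213,0.00000372,s,Pb-209,1.0,,,,ENSDF
Po-213,0.00000372,s,,,alpha,8.3760,1.0000,ENSDF
Tl-209,2.162,min,Pb-209,1.0,,,,ENSDF
Tl-209,2.162,min,,,beta_mean,0.6590,1.0000,ENSDF
Tl-209,2.162,min,,,gamma,1.56700,0.9970,ENSDF
Tl-209,2.162,min,,,gamma,0.46500,0.9690,ENSDF
Tl-209,2.162,min,,,gamma,0.11720,0.8450,ENSDF
Pb-209,3.234,h,Bi-209,1.0,,,,ENSDF
Pb-209,3.234,h,,,beta_mean,0.1978,1.0000,ENSDF
Bi-209,,,,,,,,ENSDF
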