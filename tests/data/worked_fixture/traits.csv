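genotype,condition,timepoint,replicate,fresh_weight,dry_weight,saturated_weight,osmolality,aoc,soil_water_content,co2_assimilation,stomatal_conductance,grain_yield,biomass
tolerant,drought,A,1,0.925396,0.2,1,404.483,10.1898,19.8257,19.0487,0.451057,7.78626,19.8066
tolerant,drought,A,2,0.933148,0.2,1,399.828,9.99228,19.9443,19.1096,0.446516,7.8361,19.772
tolerant,drought,B,1,0.929853,0.2,1,448.375,13.143,18.2955,17.8969,0.400666,7.90224,19.7936
tolerant,drought,B,2,0.927431,0.2,1,447.18,12.8282,19.1025,18.0345,0.395081,7.89995,19.421
tolerant,drought,C,1,0.881461,0.2,1,589.646,25.0293,13.9357,14.0505,0.251194,7.98366,19.687
tolerant,drought,C,2,0.884869,0.2,1,594.888,24.7088,13.7876,13.934,0.249912,7.78336,19.569
tolerant,drought,D,1,0.893286,0.2,1,701.012,30.1554,13.1888,11.8662,0.204333,7.7759,19.6744
tolerant,drought,D,2,0.884068,0.2,1,701.106,30.3781,13.1114,11.9437,0.202709,7.97521,19.8472
tolerant,drought,E,1,0.883204,0.2,1,742.217,24.9866,11.357,11.0402,0.171896,7.89308,19.3355
tolerant,drought,E,2,0.873547,0.2,1,736.253,25.0766,11.7604,11.1924,0.180241,7.98591,19.5554
tolerant,drought,F,1,0.936223,0.2,1,455.866,11.8495,23.8274,16.9197,0.421731,7.98217,19.6552
tolerant,drought,F,2,0.946918,0.2,1,450.428,12.2422,24.3361,17.2769,0.421613,7.87069,19.28
tolerant,well_watered,A,1,0.952515,0.2,1,394.042,9.83652,25.5525,20.1318,0.504095,10.727,28.5442
tolerant,well_watered,A,2,0.940469,0.2,1,401.593,10.0244,24.4245,20.1562,0.504927,10.7261,28.3384
tolerant,well_watered,B,1,0.946426,0.2,1,398.117,10.0354,25.0685,20.2228,0.506543,10.7445,28.2602
tolerant,well_watered,B,2,0.956836,0.2,1,400.699,10.0434,25.2512,20.1772,0.490864,10.7262,28.7997
tolerant,well_watered,C,1,0.959521,0.2,1,397.122,9.97958,24.5208,19.9545,0.503565,10.6671,28.3183
tolerant,well_watered,C,2,0.945619,0.2,1,405.667,9.94077,25.5513,19.7393,0.504009,10.4636,28.0468
tolerant,well_watered,D,1,0.945928,0.2,1,401.915,9.81408,25.166,19.8334,0.498118,10.8935,28.7718
tolerant,well_watered,D,2,0.944878,0.2,1,402.539,9.945,25.3957,19.9181,0.496966,10.6095,28.0014
tolerant,well_watered,E,1,0.952239,0.2,1,403.407,10.0422,24.9183,20.1229,0.497308,10.5885,28.6998
tolerant,well_watered,E,2,0.95489,0.2,1,398.359,10.1822,24.877,20.1557,0.502567,10.5202,28.0927
tolerant,well_watered,F,1,0.952672,0.2,1,403.784,10.1578,25.171,19.7797,0.503666,10.7628,28.1358
tolerant,well_watered,F,2,0.956708,0.2,1,393.855,10.1392,25.1503,20.0711,0.500708,10.5814,28.6608
susceptible,drought,A,1,0.933644,0.2,1,403.404,9.93896,19.2749,13.816,0.452542,1.8414,8.00045
susceptible,drought,A,2,0.923817,0.2,1,389.257,9.95814,19.4445,14.2262,0.451252,1.80047,7.86941
susceptible,drought,B,1,0.928099,0.2,1,423.677,10.9475,18.5018,12.0003,0.402507,1.84228,7.88746
susceptible,drought,B,2,0.929619,0.2,1,429.483,10.9771,18.6137,12.0765,0.397492,1.82356,7.99311
susceptible,drought,C,1,0.887143,0.2,1,458.928,12.9339,13.7022,7.96264,0.250616,1.84327,7.91339
susceptible,drought,C,2,0.878718,0.2,1,446.881,12.8887,14.3214,7.99043,0.247485,1.84341,7.96763
susceptible,drought,D,1,0.871195,0.2,1,485.605,13.8213,12.9174,5.99988,0.202665,1.83881,7.87436
susceptible,drought,D,2,0.882086,0.2,1,476.345,13.767,12.933,5.98018,0.200792,1.82471,7.8522
susceptible,drought,E,1,0.891106,0.2,1,499.96,12.0264,11.9193,6.03135,0.174627,1.84132,7.83384
susceptible,drought,E,2,0.880832,0.2,1,493.267,12.0299,11.3082,6.06773,0.176438,1.83727,7.91094
susceptible,drought,F,1,0.933809,0.2,1,422.188,9.82655,24.5712,16.3377,0.431176,1.84743,7.93146
susceptible,drought,F,2,0.937418,0.2,1,420.453,9.93589,23.5791,15.9346,0.433443,1.84822,7.92952
susceptible,well_watered,A,1,0.951757,0.2,1,405.06,10.212,24.7263,20.0628,0.51315,8.88908,16.1122
susceptible,well_watered,A,2,0.950755,0.2,1,403.275,9.90538,24.6716,20.3675,0.503653,8.86179,16.2729
susceptible,well_watered,B,1,0.957583,0.2,1,400.97,9.86556,25.091,20.0243,0.495527,8.84795,15.8026
susceptible,well_watered,B,2,0.952732,0.2,1,406.839,10.0854,24.4511,20.2739,0.498377,8.99862,16.2522
susceptible,well_watered,C,1,0.949281,0.2,1,396.388,9.94257,24.8052,20.0535,0.504909,8.8571,16.1348
susceptible,well_watered,C,2,0.950435,0.2,1,397.561,9.98542,24.8993,19.8575,0.513222,8.90466,15.7661
susceptible,well_watered,D,1,0.95192,0.2,1,394.243,10.2224,24.9141,20.1028,0.503577,8.94841,16.0075
susceptible,well_watered,D,2,0.953231,0.2,1,400.438,10.2327,25.1687,19.8115,0.497083,8.89931,16.0846
susceptible,well_watered,E,1,0.95376,0.2,1,399.065,10.1805,25.0071,20.0094,0.499219,9.02462,16.0337
susceptible,well_watered,E,2,0.950294,0.2,1,405.398,10.1682,25.097,19.4402,0.495688,8.85508,16.2675
susceptible,well_watered,F,1,0.947553,0.2,1,401.648,10.2684,24.696,19.901,0.495494,8.94553,16.116
susceptible,well_watered,F,2,0.948252,0.2,1,404.12,10.0136,25.1563,20.1572,0.505685,8.77638,15.9048
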