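metabolite_id,tolerant_D_A_r1,tolerant_D_A_r2,tolerant_D_B_r1,tolerant_D_B_r2,tolerant_D_C_r1,tolerant_D_C_r2,tolerant_D_D_r1,tolerant_D_D_r2,tolerant_D_E_r1,tolerant_D_E_r2,tolerant_D_F_r1,tolerant_D_F_r2,tolerant_W_A_r1,tolerant_W_A_r2,tolerant_W_B_r1,tolerant_W_B_r2,tolerant_W_C_r1,tolerant_W_C_r2,tolerant_W_D_r1,tolerant_W_D_r2,tolerant_W_E_r1,tolerant_W_E_r2,tolerant_W_F_r1,tolerant_W_F_r2,susceptible_D_A_r1,susceptible_D_A_r2,susceptible_D_B_r1,susceptible_D_B_r2,susceptible_D_C_r1,susceptible_D_C_r2,susceptible_D_D_r1,susceptible_D_D_r2,susceptible_D_E_r1,susceptible_D_E_r2,susceptible_D_F_r1,susceptible_D_F_r2,susceptible_W_A_r1,susceptible_W_A_r2,susceptible_W_B_r1,susceptible_W_B_r2,susceptible_W_C_r1,susceptible_W_C_r2,susceptible_W_D_r1,susceptible_W_D_r2,susceptible_W_E_r1,susceptible_W_E_r2,susceptible_W_F_r1,susceptible_W_F_r2
met_0000,14018.4,14225.6,11506.8,15223.5,90002.6,62656.6,58551.8,193225,75984.4,48838.5,24959,24550.2,20485.8,7288.32,20058.5,22547.5,13804.6,8385.27,13808.1,8181.09,14887.9,23253.5,11776.9,8108.94,17445.1,23119,7658.21,15915.4,19888.1,27683.9,30196.5,27726.9,9074.52,10247,15089.2,11151.1,15941.1,12795.9,7910.79,7071.8,19939.2,16976.5,7876.93,21094.5,11145.7,8859.49,6629.58,17088.1
met_0001,4281.26,4275.85,3492.74,4710.8,20985.6,15732.4,17513.8,55344,51477.8,30992.7,9182.59,8330.6,5907.09,2220.29,5991.86,6758.49,4151.8,2609.11,4237.46,2534.23,4539.68,6777.38,3574.06,2323.96,5389.83,6481.84,2502.03,5297.31,6622.32,8549.69,10949,9604.63,4419.96,4793.62,5346.1,3838.18,4822.32,4028.01,2441.95,2185.02,5799.3,5092.97,2245.06,6122.52,3244.98,2715.21,1951.53,5307.75
met_0002,157062,162176,94083,130102,213115,154589,82566.4,260899,181927,112372,236995,221325,231661,82906.8,229451,256088,157408,94688.2,156597,94208.2,167372,259727,132002,90006.5,200288,262521,78035.5,159329,168013,234529,229929,214209,83647.6,95352.6,174214,127043,176746,145032,92047.9,79986.9,226089,194466,87440.9,231088,124815,99575.1,73244.5,192619
met_0003,2605.84,2673.23,1561.19,2142.15,3548.99,2590.39,1368.9,4296.58,3009.33,1901.15,3877.78,3681.09,3876.69,1372.11,3738.18,4196.18,2596.55,1560.69,2638.4,1543.87,2809.43,4215.52,2215.14,1512.69,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA
met_0004,103392,106782,62329.8,85161.6,142050,102460,54525.1,172387,120330,76149.6,152598,146950,155125,54519.3,149199,166805,104934,62683.9,103841,62337.9,110440,171380,86985.4,60026.7,132577,174403,52595.4,107098,109029,154885,154204,142354,54911.2,63412.7,114425,83177.7,116856,97258.3,60095.3,52613.4,149820,130276,58167.7,153120,82767.8,64827.4,48395,129765
met_0005,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,42647.5,55168.4,16722.1,34609.9,34813,49481.3,48524.8,44523,17578.8,19987.8,36530.1,26737.8,36884.7,30686,19536,16874.9,48206.9,41216.1,18696.6,48850.6,26597.3,21062.2,15514.1,40833.9
met_0006,130069,133194,78461,104857,177085,127984,68584.6,218589,150939,95108.3,194212,182411,193880,68249.3,188484,210712,132059,78137.9,129820,78057.2,137766,214465,109383,74649.6,164424,220969,65634.7,135372,139008,192424,193661,178392,68859.4,78911.2,144513,104620,146732,120984,76831.6,65600,187025,162235,72947.1,193165,104381,81697.2,60758.2,161482
met_0007,35368.1,36115,21325.2,28941.5,47983.9,35480.1,18324,58911.3,40968.1,26132.7,53104,50373.2,52932.3,18758.3,50811.9,56560.1,35558.5,21344.5,35520,20847.6,37418,57699.8,29199.5,20377.8,44928.4,59477.3,17906.6,36714.3,37510.8,52731.4,51834.1,47918.5,18548.7,21557.9,39141.8,28484,39277.7,32727.6,20778.6,18018.4,51242.7,44022.9,19532.8,52337.2,27998.5,22392.9,16275.9,43443.2
met_0008,1695.6,1761.37,1035.71,1394.22,2321.64,1666.82,894.032,2781.91,1950.61,1236.46,2505.37,2395.35,2514.49,889.466,2433.73,2696.24,1708.15,1018.48,1703.72,1015.24,1771.17,2788.14,1405.02,961.192,2158.26,2848.7,843.147,1728.74,1777.16,2495.04,2497.2,2299.56,881.556,1025.79,1871.16,1343.22,1904.7,1571.5,1006.68,868.034,2393.18,2106.74,941.967,2512.62,1342.87,1067.21,786.582,2091.07
met_0009,46626.7,47989.4,28193,38004.7,62892.9,45534.7,24505.3,77546.3,53638.5,33526.5,69488.6,65509.8,70146.6,24528.5,68012.6,75368.3,46781.7,27627.9,46718.3,27908.9,49818.4,75664.5,39053.9,26874.4,58974.7,78257.1,23450.8,48056.3,48928.4,68650.9,68201.6,63659.9,24554.7,28517.8,50516.8,37061.3,52196,43269.6,27270.5,23516.2,67263.5,58151,26053.6,68282.3,37084.6,29521.8,21867.2,57786.8
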