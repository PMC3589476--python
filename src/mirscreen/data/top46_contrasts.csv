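# The 46 plasma miRNAs differentially expressed between pre-resection breast
# cancer cases and controls (p<0.05, >=2-fold) in the screening study:
# background-subtracted quantile-normalized group mean intensities for the
# four cohorts and the three contrast p-values (control vs pre-resection,
# control vs post-resection, control vs other cancers), as printed.
# Censored entries are stored as "<bound" and parsed as their upper bound.
mirna,mean_control,mean_bc_pre,mean_bc_post,mean_other,p_case,p_post,p_other
miR-1184,606.7,2248.4,1434.8,5581.4,0.0002,0.084,0.0001
miR-376c,1681.5,4011.3,4204.7,5898.1,0.0003,0.0020,0.0004
miR-30b*,44.2,19.6,33.6,12.6,0.0003,0.14,0.0004
miR-200a*,20.9,126.1,81.3,330.7,0.0009,0.061,<0.0001
miR-1295,37.2,94.8,66.3,264.9,0.0010,0.073,0.0027
HS_303_b,274.8,83.4,165.5,61.9,0.0011,0.072,0.0096
miR-34c-5p,28.3,328.5,124.1,804.6,0.0016,0.083,<0.0001
HS_276.1,131.6,429.4,323.6,917.1,0.0020,0.032,<0.0001
HS_123,36.3,108.3,167.4,300.0,0.0020,0.22,0.0015
miR-187*,81.7,989.6,517.9,2422.7,0.0024,0.065,<0.0001
miR-376a,524.2,2062.3,1630.0,4388.1,0.0029,0.014,0.0030
miR-379,533.5,1566.0,1023.6,4098.1,0.0030,0.091,0.0013
miR-876-5p,24.8,12.7,16.0,11.1,0.0033,0.035,0.051
miR-377,431.4,1505.4,1582.6,3068.8,0.0033,0.0074,<0.0001
miR-202*,149.5,2134.3,1722.9,7324.8,0.0035,0.059,<0.0001
miR-376b,354.9,1159.3,1455.9,2275.8,0.0035,0.0064,<0.0001
miR-30c-2*,10.2,37.3,35.5,210.1,0.0038,0.018,0.033
miR-1179,176.0,1405.7,1257.4,2278.0,0.0042,0.035,<0.0001
miR-623,247.0,1951.5,1249.7,5334.7,0.0044,0.13,0.0003
miR-518e,34.2,103.6,73.1,291.3,0.0046,0.12,<0.0001
miR-587,17.3,36.3,26.0,283.4,0.0051,0.12,0.047
HS_242,145.1,1589.7,1033.1,3971.6,0.0056,0.050,0.0012
miR-193b*,235.4,84.5,246.5,68.8,0.0062,0.90,0.027
miR-1197,80.6,1833.8,1286.6,5082.4,0.0064,0.049,0.0003
miR-33b,658.7,261.0,527.0,24.2,0.0073,0.45,0.0013
miR-708*,190.5,80.8,145.0,347.2,0.0081,0.30,0.43
miR-1304,100.4,1207.5,1398.4,4469.0,0.0083,0.053,<0.0001
miR-1261,37.8,18.9,23.5,10.2,0.0092,0.043,0.0036
miR-380,151.0,2224.2,1308.4,5256.7,0.0092,0.078,<0.0001
miR-490-3p,35.9,17.7,46.4,5.8,0.011,0.35,0.0014
HS_304_b,19.2,43.7,37.6,46.4,0.011,0.049,0.0007
miR-940,2006.3,4695.4,3774.3,7062.9,0.012,0.099,<0.0001
miR-1180,238.1,697.9,723.9,2538.2,0.013,0.079,<0.0001
miR-671-3p,126.5,691.7,566.3,3068.5,0.014,0.032,0.0004
miR-654-5p,231.2,994.7,459.0,2315.0,0.014,0.22,<0.0001
miR-380*,126.6,759.4,496.9,2352.3,0.018,0.12,0.0002
HS_149,75.6,607.1,514.5,1857.7,0.019,0.064,0.019
miR-92b*,159.3,61.5,96.3,98.9,0.019,0.156,0.33
miR-1238,3210.5,8019.5,7376.7,12290.8,0.019,0.053,<0.0001
miR-612,32.8,1050.2,423.7,2872.0,0.022,0.093,0.0006
miR-299-5p,30.2,101.9,295.5,356.7,0.029,0.064,0.015
miR-646,194.9,902.0,1118.6,3544.8,0.030,0.051,0.0020
miR-127-3p,111.0,261.1,354.7,270.6,0.042,0.022,0.15
miR-378*,143.2,814.9,982.8,2352.0,0.043,0.097,0.00074
miR-568,31.2,301.2,71.0,265.1,0.044,0.37,0.17
miR-202,40.3,102.3,79.4,266.1,0.050,0.28,<0.0001
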