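# Cross-evaluation table: the screening study's 46 top candidate miRNAs
# (p<0.05, >=2-fold, pre-resection cases vs controls) with each probe's log2
# fold change and unadjusted p-value in the study's own dataset ("current")
# and in the comparison plasma oligoarray dataset ("zhao"). Values as
# printed; the sign convention of the log2 FC column is preserved verbatim
# even where it disagrees with the group-mean table for the same probes.
mirna,log2_fc_current,p_current,log2_fc_zhao,p_zhao
miR-92b*,-1.72,0.019,0.53,0.25
miR-202,-1.48,0.05,0.23,0.44
miR-1197,-1.37,0.0064,-0.02,0.97
miR-376c,-1.34,0.0003,-0.84,0.23
miR-1295,-1.24,0.001,-0.03,0.95
miR-568,-1.17,0.044,0.25,0.62
miR-187*,-1.02,0.0024,0.15,0.61
HS_304_b,-1.00,0.011,0.09,0.63
miR-202*,-0.96,0.0035,-0.06,0.41
HS_123,1.07,0.002,-0.05,0.80
miR-200a*,1.19,0.0009,0.06,0.86
miR-380,1.23,0.0092,-0.54,0.48
miR-1238,1.23,0.019,-0.04,0.83
miR-376b,1.25,0.0035,0.28,0.68
HS_276.1,1.32,0.002,0.15,0.64
miR-34c-5p,1.34,0.0016,-0.24,0.17
miR-490-3p,1.34,0.050,0.03,0.66
miR-30c-2*,1.35,0.0038,-0.05,0.56
miR-1179,1.55,0.0042,-0.78,0.40
miR-378*,1.55,0.043,-0.55,0.06
miR-127-3p,1.58,0.042,0.17,0.74
miR-876-5p,1.60,0.0033,-0.02,0.88
miR-376a,1.71,0.0029,0.91,0.21
miR-612,1.71,0.022,-0.15,0.87
miR-1184,1.75,0.0002,0.19,0.78
miR-193b*,1.80,0.0062,0.30,0.46
miR-708*,1.87,0.0081,0.05,0.92
miR-30b*,1.89,0.0003,0.11,0.27
miR-671-3p,1.98,0.014,0.38,0.51
miR-379,2.11,0.003,1.10,0.22
miR-587,2.21,0.0051,-0.41,0.47
miR-33b,2.45,0.0073,-0.23,0.33
miR-654-5p,2.51,0.014,-1.58,0.06
miR-623,2.51,0.043,0.10,0.91
miR-1180,2.59,0.013,0.05,0.95
miR-377,2.59,0.0033,-1.08,0.05
miR-940,2.98,0.012,0.17,0.30
miR-380*,3.00,0.018,-0.14,0.82
HS_149,3.00,0.019,-0.15,0.82
miR-1304,3.27,0.044,-2.52,0.002
miR-299-5p,3.27,0.029,0.24,0.69
miR-1261,3.45,0.0092,0.12,0.17
miR-646,3.54,0.03,-0.25,0.70
HS_303_b,3.59,0.0011,-0.20,0.25
miR-518e,3.60,0.0046,0.30,0.29
HS_242,3.84,0.0056,0.46,0.61
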