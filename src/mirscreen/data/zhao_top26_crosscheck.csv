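# Converse cross-evaluation table: the comparison study's 26 top candidate
# miRNAs (p<0.05, >=2-fold, 20 cases vs 20 controls, plasma oligoarray) with
# each probe's log2 fold change and unadjusted p-value in that dataset
# ("zhao") and in the screening study's own dataset ("current"). Values as
# printed.
mirna,log2_fc_zhao,p_zhao,log2_fc_current,p_current
miR-595,2.40,0.0024,1.44,0.30
miR-589,2.16,0.0070,0.80,0.35
miR-504,1.92,0.0258,1.44,0.13
miR-518b,1.60,0.0353,1.09,0.31
miR-483-5p,1.39,0.0372,-0.76,0.11
miR-425*,1.20,0.0271,-0.24,0.20
miR-493,1.14,0.0329,1.03,0.40
miR-187,1.14,0.0383,0.27,0.79
miR-431*,1.11,0.0258,3.45,0.11
miR-1231,1.03,0.0239,-0.18,0.80
solexa-9655-85,1.00,0.0265,-0.42,0.05
miR-668,-1.00,0.0385,0.37,0.10
miR-377,-1.08,0.0485,1.78,0.0039
miR-410,-1.17,0.0400,0.79,0.17
miR-922,-1.24,0.0300,-0.13,0.55
miR-155,-1.27,0.0141,-0.40,0.11
HS_169,-1.29,0.0230,1.17,0.60
miR-340*,-1.51,0.0199,0.12,0.83
HS_200,-1.53,0.0494,-0.40,0.24
miR-432,-1.60,0.0476,0.09,0.81
miR-574-3p,-1.67,0.0379,0.05,0.79
miR-148a,-1.68,0.0348,-0.04,0.85
miR-181a,-2.00,0.0044,0.02,0.89
miR-1275,-2.01,0.0081,-4.17,0.10
miR-1304,-2.51,0.0027,3.47,0.015
miR-151-5p,-2.82,0.0005,0.32,0.0036
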