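# Metadata for the five genome-wide circulating-miRNA profiling studies in
# breast cancer: platform, substrate, normalization, cohort sizes, and the
# total number of candidate miRNAs each reported (the concordance
# denominator: 85+10+25+12+26 = 158).
study,platform,substrate,normalization,n_cases,n_controls,n_candidates
Wu,SOLiD,serum,total reads,13,10,85
Hu,Illumina GAIIx,serum,miR-191/484,48,48,10
Schrauder,Geniom oligoarray,whole blood,VSN,48,57,25
Sieuwerts,TaqMan array,CTCs,avg 28-miR,41,8,12
Zhao,Illumina oligoarray,plasma,quantile,20,20,26
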