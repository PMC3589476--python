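# Directional calls for the 16 miRNAs reported as differentially expressed by
# at least two of the five genome-wide circulating-miRNA profiling studies in
# breast cancer (cases vs controls). One row per (study, miRNA) report;
# fold_change is the reported magnitude (always > 1; the direction column
# carries the sign). Only the overlapping subset of each study's candidate
# list is transcribed; full per-study candidate counts live in
# genomewide_studies.csv.
study,mirna,direction,fold_change
Schrauder,miR-497,up,1.8
Sieuwerts,miR-497,up,2.9
Wu,miR-451,up,67.8
Hu,miR-451,up,6.5
Wu,miR-25,up,10.7
Hu,miR-25,up,56.0
Wu,miR-222,up,1.9
Hu,miR-222,up,4.8
Wu,miR-31,down,11.1
Sieuwerts,miR-31,down,1.4
Wu,miR-151-5p,down,1.5
Zhao,miR-151-5p,down,7.1
Wu,miR-30a,down,20.0
Hu,miR-30a,up,5.0
Wu,miR-106b,down,4.4
Schrauder,miR-106b,up,1.7
Wu,miR-210,down,4.4
Sieuwerts,miR-210,up,8.1
Wu,let-7b,down,3.9
Hu,let-7b,up,4.1
Wu,miR-24,up,26.7
Schrauder,miR-24,down,1.8
Wu,miR-200c,up,2.9
Sieuwerts,miR-200c,down,1.4
Wu,miR-155,up,1.2
Zhao,miR-155,down,2.4
Wu,miR-148a,up,9.0
Zhao,miR-148a,down,3.2
Wu,miR-181a,up,5.5
Zhao,miR-181a,down,4.0
Schrauder,miR-922,up,1.7
Zhao,miR-922,down,2.4
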