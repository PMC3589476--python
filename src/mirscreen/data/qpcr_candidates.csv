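# Candidate circulating miRNAs reported by ten qPCR (pre-selected probe set)
# profiling studies of breast cancer cases vs healthy controls, harmonized as
# simple directional fold changes. One row per (study, miRNA) report; names as
# printed in the source studies (normalized on load). Empty fold_change means
# the study reported direction only. "U6" is a snRNA carried as a generic
# entry name.
study,mirna,direction,fold_change,substrate,n_cases,n_controls
Wang,miR-21,up,2.5,serum,58,40
Asaga,miR-21,up,,serum,102,20
Wu_qpcr,miR-21,up,2,serum,20,20
Roth,miR-155,up,1.6,serum,30,29
Wang,miR-155,up,3.5,serum,58,40
Appaiah,U6,up,1.5,serum,75,68
Heneghan,let7a,up,11.2,whole blood,83,44
Roth,miR-10b,up,4,serum,30,29
Wu_qpcr,miR-29a,up,2,serum,20,20
Roth,miR-34a,up,4.5,serum,30,29
Wang,miR-106a,up,1.9,serum,58,40
Wang,miR-126,down,2,serum,58,40
Heneghan,miR-195,up,19.3,whole blood,83,44
Wang,miR-199a,down,2,serum,58,40
Schwarzenbach,miR-214,up,5,serum,102,85
van_Schooneveld,miR-215,down,2,serum,71,20
van_Schooneveld,miR-299-5p,down,2,serum,71,20
Wang,miR-335,down,2,serum,58,40
van_Schooneveld,miR-411,down,2,serum,71,20
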