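# Study-population summary for the four plasma cohorts: age (mean, SD) and
# race counts (African-American / Caucasian) per cohort.
cohort,n,age_mean,age_sd,n_african_american,n_caucasian
control,20,54.9,9.1,4,16
bc_pre,20,53.7,9.9,2,18
bc_post,20,58.8,9.7,5,15
other_cancer,10,64.2,5.5,4,6
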