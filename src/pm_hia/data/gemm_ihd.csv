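# GEMM coefficients for ischemic heart disease (ICD-10 I20-I25) mortality.
# Transcribed from the published Global Exposure Mortality Model supplementary
# tables (41-cohort fit including the Chinese male cohort); age-specific
# log-risk coefficients with shared supra-linear shape constants.
# alpha: 1.9
# mu: 12.0
# nu: 40.2
# counterfactual_conc: 2.4
# source_version: "GEMM 2018, IHD, incl. Chinese cohort (transcribed)"
cause,age_group,theta,theta_se
IHD,25-29,0.1938,0.0119
IHD,30-34,0.1751,0.0106
IHD,35-39,0.1614,0.0100
IHD,40-44,0.1431,0.0090
IHD,45-49,0.1282,0.0081
IHD,50-54,0.1143,0.0073
IHD,55-59,0.1032,0.0066
IHD,60-64,0.0915,0.0059
IHD,65-69,0.0818,0.0053
IHD,70-74,0.0702,0.0047
IHD,75-79,0.0600,0.0042
IHD,80+,0.0474,0.0037
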