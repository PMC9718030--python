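# GEMM NCD+LRI age-specific hazard-ratio parameters (41-cohort pooled fit,
# including the Chinese cohort), Burnett et al. 2018, PNAS 115(38):9592-9597,
# supplementary materials. HR(z) = exp(theta*log(1+z/alpha)*omega(z)),
# omega(z) = 1/(1+exp(-(z-mu)/nu)), z = max(0, C - 2.4 ug/m3).
# The published table's terminal band is 80+; its parameters are carried by
# both the 80-84 and 85+ rows here.
# file version: 1
age_group,theta,theta_se,alpha,mu,nu
25-29,0.1585,0.01477,1.6,15.5,36.8
30-34,0.1577,0.01470,1.6,15.5,36.8
35-39,0.1570,0.01463,1.6,15.5,36.8
40-44,0.1558,0.01450,1.6,15.5,36.8
45-49,0.1532,0.01425,1.6,15.5,36.8
50-54,0.1499,0.01394,1.6,15.5,36.8
55-59,0.1462,0.01361,1.6,15.5,36.8
60-64,0.1421,0.01325,1.6,15.5,36.8
65-69,0.1374,0.01284,1.6,15.5,36.8
70-74,0.1319,0.01234,1.6,15.5,36.8
75-79,0.1253,0.01174,1.6,15.5,36.8
80-84,0.1141,0.01071,1.6,15.5,36.8
85+,0.1141,0.01071,1.6,15.5,36.8
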