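# Printed longitudinal lesion/deposit counts per monthly cluster (VLDLR mutants):
# n_eyes = eyes evaluated; lesions_mean/sd = lesions per eye; deposits_total =
# depolarizing deposits summed over eyes; deposits_mean/sd = per eye.
month,n_eyes,lesions_mean,lesions_sd,deposits_total,deposits_mean,deposits_sd
1,5,4.80,2.05,0,0,0
2,14,6.21,2.52,26,1.86,1.35
3,14,6.29,3.10,53,3.79,2.36
4,15,5.80,2.73,63,4.20,2.68
5,13,5.23,2.59,32,2.46,1.39
6,14,6.21,2.52,55,3.92,1.98
7,10,5.10,1.66,38,3.80,2.35
8,15,5.80,2.18,72,4.80,2.81
9,16,6.31,2.55,69,4.31,2.30
10,14,5.93,2.34,45,3.21,2.04
11,8,6.38,2.62,33,4.13,2.03
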