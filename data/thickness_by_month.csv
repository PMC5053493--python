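# Printed monthly retinal thickness summary (µm): total retina (TR) and outer
# retina (OR), mean and sample sd across eyes, for the mutant and control groups.
group,month,n_eyes,tr_mean,tr_sd,or_mean,or_sd
mutant,1,3,212.80,1.74,90.11,3.38
mutant,2,13,206.62,9.14,85.94,4.00
mutant,3,13,199.84,11.36,80.49,6.94
mutant,4,14,196.30,11.13,78.03,7.44
mutant,5,13,191.46,14.12,73.17,8.72
mutant,6,14,192.72,10.60,74.47,6.77
mutant,7,9,191.99,10.16,75.00,6.01
mutant,8,15,190.35,11.08,73.50,7.30
mutant,9,16,189.13,10.92,72.58,7.62
mutant,10,14,188.62,12.03,72.27,7.43
mutant,11,8,187.41,12.94,71.55,8.84
control,2,6,209.40,4.10,95.05,2.44
control,3,7,205.21,4.88,93.37,3.54
control,8,8,206.43,2.59,94.96,2.22
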