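age_group,population
50-54,1387000
55-59,1293000
60-64,1049000
65-69,819000
70-74,671000
75-79,580000
80-84,457000
85-89,256000
90-94,107000
95+,28000
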