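age,weight
<5,0.0886
5-9,0.0869
10-14,0.0860
15-19,0.0847
20-24,0.0822
25-29,0.0793
30-34,0.0761
35-39,0.0715
40-44,0.0659
45-49,0.0604
50-54,0.0537
55-59,0.0455
60-64,0.0372
65-69,0.0296
70-74,0.0221
75-79,0.0152
80-84,0.0091
85-89,0.0044
90-94,0.0015
95+,0.0004
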