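# hPTP1E PDZ2: published hot-residue list (χ > 1.0) from the perturbation
# response scan of the apo crystal structure, author numbering.
11
13
17
18
19
20
21
22
23
24
25
34
35
36
37
38
39
40
41
45
46
58
59
60
61
66
69
71
73
74
75
76
77
78
79
80
81
85
87
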