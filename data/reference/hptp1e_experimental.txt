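# hPTP1E PDZ2: the ten residues whose side-chain dynamics change on peptide
# binding (NMR methyl relaxation, RA-GEF2 and APC peptides; author numbering).
6
20
22
26
30
41
61
64
78
85
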