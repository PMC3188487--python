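# PSD-95 PDZ3: the eight experimentally supported allosteric residues
# (double-mutant cycle coupling) that the response-ratio scan recovers at
# threshold 1.0. The full eleven-residue experimental list appears only in
# supplementary material that is not distributed here.
328
329
340
341
362
372
386
390
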