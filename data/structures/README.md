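# Crystal structures (user-supplied)

The benchmark comparisons against the published PDZ results need three PDB
entries that cannot be redistributed with this repository. To run them,
download and place here (lower-case names):

- `3lnx.pdb` — hPTP1E PDZ2, unbound crystal structure
- `1bfe.pdb` — PSD-95 PDZ3, unbound crystal structure
- `1be9.pdb` — PSD-95 PDZ3 bound to the CRIPT peptide

e.g. `wget https://files.rcsb.org/download/1BFE.pdb -O 1bfe.pdb`

All synthetic-geometry tests and the acceptance script run without these
files; only the crystal-structure benchmark tests consume them.
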