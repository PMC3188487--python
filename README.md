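# prscan

Perturbation response scanning (PRS) on a cutoff-free Cα elastic network,
for locating allosterically responsive residues in single protein domains,
tracing the intramolecular pathway that carries the signal, and generating
perturbation-displaced backbone ensembles for flexible docking.

## Who this is for

Structural bioinformaticians studying single-domain allostery — the paradigm
systems being PDZ domains, where ligand binding at the peptide groove changes
dynamics (and binding affinity) at surfaces that never touch the ligand.
Given an unbound crystal structure and a binding-pocket residue selection,
`prscan` answers: *which residues feel a push at the binding site, and along
which chain of residues does the push propagate?*

## The model

The protein is reduced to its Cα atoms, joined by harmonic springs. Instead
of an interaction cutoff, **every** residue pair *i, j* interacts with a
spring constant weighted by the inverse square of its separation:

    k_ij = γ_b = 1            if |i − j| = 1 in sequence (bonded)
    k_ij = c / r_ij²,  c = 8  otherwise

which removes the arbitrary cutoff radius of conventional elastic network
models. The 3N×3N Hessian **H** of this network and linear response theory
give the equilibrium displacement field for an external force **ΔF**:

    ΔR = H⁺ ΔF        (H⁺ = Moore–Penrose pseudo-inverse, 6 rigid modes dropped)

A unit force is applied to each residue *i* in turn along 7 directions
(±axes, face diagonals, body diagonal, all unit-normalized), and the squared
displacement magnitude of every residue *j* is recorded as A_ij. The
**allosteric response ratio** of residue *j* is

    χ_j = max over directions of  ⟨A_ij⟩_{i ∈ binding pocket} / ⟨A_ij⟩_{i ∈ all residues}

Residues with χ_j > 1 respond more strongly to binding-site perturbation
than to an average perturbation — the *hot* residues. For the pathway, the
3×3 block of H⁺ coupling residue *k* to each pocket residue is decomposed
(SVD); the dominant singular vector is the direction *k* predominantly moves
in. Hot residues (±1 sequence neighbor, window 3) whose dominant directions
align — mean |cos θ| ≥ 0.98 — are linked, and exact dynamic programming over
the sequence-ordered DAG returns the maximal chain with the largest product
of overlap coefficients: the predicted signaling pathway.

## Worked example

Scan a synthetic 60-residue structure with residues 1–6 as the "binding
pocket" (no downloads needed):

```console
$ prscan fixture --kind random_cloud --n 60 --seed 1 --out cloud.pdb
wrote 60-residue random_cloud to cloud.pdb
$ prscan scan --pdb cloud.pdb --pocket 1-6 --out chi.tsv
6 hot residues (chi > 1.0): A:3, A:1, A:5, A:2, A:6, A:4
chi profile written to chi.tsv
```

In an isotropic random cloud only the perturbed residues themselves exceed
the χ = 1 baseline — there is no structural anisotropy to carry the signal,
so the hot set collapses onto the pocket. A regular helical geometry behaves
differently:

```console
$ prscan fixture --kind ideal_helix --n 60 --out helix.pdb
$ prscan pathway --pdb helix.pdb --pocket 1-6 --out pw.json
pathway: ALA7 -> ALA52
total weight: 0.9983
```

Here the periodic geometry couples distant residues into a common response
direction: residues 7 and 52 move along lines whose mean absolute cosine is
0.9983, so the maximum-weight pathway links them across 45 positions. On a
real PDZ domain (e.g. PSD-95 PDZ3 with pocket `320-328,371-380`) the same
command returns the chain of hot residues connecting the binding groove to
the distal surfaces, with one overlap coefficient per link and their product
as the pathway weight.

Python API, estimator-style:

```python
from prscan import PerturbationResponseScanner, read_structure

model = read_structure("data/structures/1bfe.pdb")
scanner = PerturbationResponseScanner().fit(model)   # network + 7-direction scan
profile = scanner.chi_profile("320-328,371-380")     # χ per residue
hot = scanner.hot_residues("320-328,371-380")        # χ > 1, descending
```

Other subcommands: `prscan ensemble` (multi-MODEL PDB of response-displaced
conformers), `prscan evaluate` (contingency table + Fisher's exact test
against a reference residue list), `prscan rmsd` (superposition RMSD between
two structures), `prscan run-all` (full pipeline with TSV/JSON/plot output).

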