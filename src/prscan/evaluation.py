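"""Agreement statistics and structural benchmarks.

Predicted hot residues are compared with reference residue sets
(experimental mutagenesis/NMR lists, evolutionary-coupling lists) through a
2×2 contingency table over the analyzed chain's residues and Fisher's exact
test. Structural similarity between constructs is measured as the RMSD
after least-squares superposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa
from Bio.SVDSuperimposer import SVDSuperimposer

from .structures import CalphaModel

__all__ = [
    "ContingencyTable",
    "contingency_table",
    "fisher_exact",
    "kabsch_rmsd",
    "paired_atom_coords",
    "match_report",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 pattern-matching table over a stated residue universe.

    counts = ((both, predicted only), (reference only, neither)).
    """

    counts: tuple[tuple[int, int], tuple[int, int]]
    universe_size: int

    def __post_init__(self) -> None:
        flat = [x for row in self.counts for x in row]
        if any(x < 0 for x in flat):
            raise ValueError("negative cell count")
        if sum(flat) != self.universe_size:
            raise ValueError("cells do not sum to the universe size")

    def as_array(self) -> np.ndarray:
        return np.array(self.counts, dtype=int)


def contingency_table(predicted: set, reference: set, universe: set,
                      near_miss: int = 0) -> ContingencyTable:
    """Cross-tabulate predicted vs reference residues over a universe.

    ``near_miss`` > 0 counts a predicted residue as matching when a reference
    residue lies within that many sequence positions (off by default;
    elements must then be plain residue numbers).
    """
    predicted, reference, universe = set(predicted), set(reference), set(universe)
    bad = (predicted | reference) - universe
    if bad:
        raise ValueError(f"residues outside the universe: {sorted(bad)}")
    if near_miss > 0:
        matched_pred = {
            p for p in predicted
            if any(abs(int(p) - int(r)) <= near_miss for r in reference)
        }
    else:
        matched_pred = predicted & reference
    both = len(matched_pred & reference) if near_miss == 0 else len(
        {r for r in reference
         if any(abs(int(r) - int(p)) <= near_miss for p in predicted)})
    pred_only = len(predicted) - len(matched_pred)
    ref_only = len(reference) - both
    neither = len(universe) - (both + pred_only + ref_only)
    return ContingencyTable(
        counts=((both, pred_only), (ref_only, neither)),
        universe_size=len(universe),
    )


def fisher_exact(t: ContingencyTable, alternative: str = "two-sided") -> float:
    """Fisher's exact p-value for the table.

    Two-sided by the probability-mass rule: the p-value sums the
    hypergeometric probabilities of every table with the observed margins
    whose point probability does not exceed the observed table's. Computed
    with exact rational arithmetic (the hypergeometric probabilities of a
    2×2 table with fixed margins are rationals), so ties are resolved
    exactly rather than to floating tolerance.
    """
    (a, b), (c, d) = t.counts
    r1, c1, n = a + b, a + c, t.universe_size
    lo, hi = max(0, c1 - (c + d)), min(r1, c1)
    if lo == hi:  # a zero/degenerate margin leaves a single feasible table
        return 1.0
    # P(x) = C(r1, x) C(n - r1, c1 - x) / C(n, c1); compare numerators only
    weights = {x: comb(r1, x) * comb(n - r1, c1 - x) for x in range(lo, hi + 1)}
    total = sum(weights.values())
    if alternative == "two-sided":
        mass = sum(w for w in weights.values() if w <= weights[a])
    elif alternative == "greater":
        mass = sum(w for x, w in weights.items() if x >= a)
    elif alternative == "less":
        mass = sum(w for x, w in weights.items() if x <= a)
    else:
        raise ValueError("alternative must be 'two-sided', 'greater' or 'less'")
    return float(Fraction(mass, total))


def _extract_coords(x) -> np.ndarray:
    if isinstance(x, CalphaModel):
        return x.coords
    return np.asarray(x, dtype=float)


def kabsch_rmsd(a, b) -> float:
    """RMSD after optimal rigid superposition of two paired coordinate sets.

    Inputs are CalphaModels or (M, 3) arrays whose rows are already paired
    (same residue/atom order). Superposition is the least-squares optimal
    rotation + translation.
    """
    xa, xb = _extract_coords(a), _extract_coords(b)
    if xa.shape != xb.shape:
        raise ValueError(f"coordinate sets differ in shape: {xa.shape} vs {xb.shape}")
    if xa.shape[0] < 3:
        raise ValueError("need at least 3 paired points for superposition")
    sup = SVDSuperimposer()
    sup.set(xa, xb)
    sup.run()
    return float(sup.get_rms())


def paired_atom_coords(path_a: str | Path, path_b: str | Path,
                       chain_a: str | None = None, chain_b: str | None = None,
                       selection: str = "backbone") -> tuple[np.ndarray, np.ndarray]:
    """All-atom reader for the structure benchmark.

    Pairs atoms of two PDB files by (author residue number, atom name) over
    the residues common to both selected chains. ``selection`` is
    ``"backbone"`` (N, CA, C, O), ``"ca"``, or ``"all"`` (all shared heavy
    atoms; hydrogens excluded).
    """

    def atoms_of(path, chain):
        parser = PDBParser(QUIET=True)
        model = next(iter(parser.get_structure("s", str(path))))
        chains = [c for c in model if chain is None or c.id == chain]
        out: dict[tuple[int, str, str], np.ndarray] = {}
        for ch in chains:
            found = False
            for res in ch:
                het, resseq, icode = res.get_id()
                if het.strip() or not is_aa(res, standard=False):
                    continue
                for atom in res.get_atoms():
                    name = atom.get_name()
                    if atom.element == "H":
                        continue
                    if selection == "backbone" and name not in BACKBONE_ATOMS:
                        continue
                    if selection == "ca" and name != "CA":
                        continue
                    out[(resseq, icode.strip(), name)] = np.array(atom.get_coord())
                    found = True
            if chain is None and found:
                break
        return out

    aa = atoms_of(path_a, chain_a)
    bb = atoms_of(path_b, chain_b)
    keys = sorted(set(aa) & set(bb))
    if len(keys) < 3:
        raise ValueError("fewer than 3 paired atoms between the two structures")
    return (np.array([aa[k] for k in keys]), np.array([bb[k] for k in keys]))


def match_report(predicted: set, reference: set, universe: set,
                 near_miss: int = 0) -> dict:
    """Contingency table plus Fisher p-value in one call."""
    table = contingency_table(predicted, reference, universe, near_miss=near_miss)
    return {
        "table": table,
        "n_overlap": table.counts[0][0],
        "n_predicted": table.counts[0][0] + table.counts[0][1],
        "n_reference": table.counts[0][0] + table.counts[1][0],
        "p_value": fisher_exact(table),
    }
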