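"""Coarse-grained structure I/O.

Reads PDB files into Cα-only models (the node set of the elastic network),
parses binding-pocket residue selections given in author numbering, and
writes displaced-coordinate ensembles back out as multi-MODEL PDB files.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa

__all__ = [
    "CalphaModel",
    "BindingPocket",
    "StructureError",
    "read_structure",
    "parse_pocket_spec",
    "write_ensemble",
    "read_reference_set",
]


class StructureError(ValueError):
    """Raised for malformed or empty structure selections."""


ResidueId = tuple[str, int, str]  # (chain id, author residue number, insertion code)


@dataclass
class CalphaModel:
    """Ordered Cα nodes of a protein chain.

    Residue identity is the author residue number plus insertion code, so
    reported residues line up with the numbering used in the literature;
    matrices over the model use dense 0-based indices in file order.
    """

    residue_ids: list[ResidueId]
    residue_names: list[str]
    coords: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.residue_ids)
        if n < 2:
            raise StructureError(f"need at least 2 residues, got {n}")
        if self.coords.shape != (n, 3):
            raise StructureError(
                f"coords shape {self.coords.shape} does not match {n} residues"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        if len(self.residue_names) != n:
            raise StructureError("residue_names length mismatch")
        if len(set(self.residue_ids)) != n:
            seen: set[ResidueId] = set()
            for rid in self.residue_ids:
                if rid in seen:
                    raise StructureError(f"duplicate residue id {rid}")
                seen.add(rid)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def author_numbers(self) -> list[int]:
        return [rid[1] for rid in self.residue_ids]

    def index_of(self, number: int, chain: str | None = None, icode: str = "") -> int:
        hits = [
            i
            for i, (ch, num, ic) in enumerate(self.residue_ids)
            if num == number and ic == icode and (chain is None or ch == chain)
        ]
        if not hits:
            raise KeyError(f"residue {number}{icode or ''} not in model")
        if len(hits) > 1:
            raise KeyError(f"residue {number} ambiguous across chains; give a chain id")
        return hits[0]

    def label(self, index: int) -> str:
        """Human-readable residue label like 'HIS372'."""
        ch, num, ic = self.residue_ids[index]
        return f"{self.residue_names[index]}{num}{ic}".strip()

    def bonded_pairs(self) -> np.ndarray:
        """Index pairs whose author numbers differ by exactly 1 in the same chain.

        Residues missing from the file break the chain: no spring bridges a
        numbering gap, so a gap never acquires a spuriously stiff bond.
        """
        pairs = []
        for i in range(self.n_residues - 1):
            ch_i, num_i, _ = self.residue_ids[i]
            ch_j, num_j, _ = self.residue_ids[i + 1]
            if ch_i == ch_j and num_j - num_i == 1:
                pairs.append((i, i + 1))
        return np.array(pairs, dtype=int).reshape(-1, 2)

    def with_coords(self, coords: np.ndarray, source_label: str | None = None) -> "CalphaModel":
        return CalphaModel(
            residue_ids=list(self.residue_ids),
            residue_names=list(self.residue_names),
            coords=np.array(coords, dtype=float),
            source_label=self.source_label if source_label is None else source_label,
        )

    def drop_residues(self, numbers: Iterable[int], chain: str | None = None) -> "CalphaModel":
        """Model with the listed author-numbered residues removed (e.g. a
        truncated construct missing a terminal helix)."""
        drop = set(numbers)
        keep = [
            i
            for i, (ch, num, _) in enumerate(self.residue_ids)
            if not (num in drop and (chain is None or ch == chain))
        ]
        if len(keep) == self.n_residues:
            warnings.warn("drop_residues removed nothing", stacklevel=2)
        return CalphaModel(
            residue_ids=[self.residue_ids[i] for i in keep],
            residue_names=[self.residue_names[i] for i in keep],
            coords=self.coords[keep],
            source_label=self.source_label + "-truncated",
        )


@dataclass
class BindingPocket:
    """Perturbation sites: binding-pocket residues resolved to model indices."""

    residue_selectors: list[int]
    resolved_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.resolved_indices:
            raise StructureError("binding pocket resolved to no residues")
        if len(set(self.resolved_indices)) != len(self.resolved_indices):
            raise StructureError("binding pocket indices not unique")


def _pick_calpha(residue):
    """Cα coordinate for a residue: highest-occupancy altloc, ties broken by
    altloc letter order. Returns None when the residue has no Cα."""
    if "CA" not in residue:
        return None
    atom = residue["CA"]
    if atom.is_disordered():
        children = sorted(
            atom.disordered_get_list(),
            key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
        )
        atom = children[0]
    return np.array(atom.get_coord(), dtype=float)


def read_structure(
    path: str | Path,
    chain: str | None = None,
    model_index: int = 0,
) -> CalphaModel:
    """Read a PDB file into a Cα model.

    Parameters
    ----------
    path : PDB file with ATOM records (MODEL/ENDMDL honored).
    chain : chain id to select; ``None`` takes the first chain containing a
        protein Cα (crystal forms with several copies default to the first).
    model_index : which MODEL block to use (0-based).
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    models = list(structure)
    if model_index >= len(models):
        raise StructureError(
            f"model index {model_index} out of range ({len(models)} models)"
        )
    model = models[model_index]

    chains = [c for c in model if chain is None or c.id == chain]
    residue_ids: list[ResidueId] = []
    residue_names: list[str] = []
    coords: list[np.ndarray] = []
    chosen_chain: str | None = None
    for ch in chains:
        has_ca = False
        for res in ch:
            hetflag, resseq, icode = res.get_id()
            if hetflag.strip():  # HETATM / waters excluded
                continue
            if not is_aa(res, standard=False):
                continue
            xyz = _pick_calpha(res)
            if xyz is None:
                continue
            has_ca = True
            rid = (ch.id, resseq, icode.strip())
            if rid in set(residue_ids):
                raise StructureError(
                    f"duplicate residue {ch.id}:{resseq}{icode} after altloc resolution"
                )
            residue_ids.append(rid)
            residue_names.append(res.get_resname().strip())
            coords.append(xyz)
        if chain is None and has_ca:
            chosen_chain = ch.id
            break  # first protein chain only, unless a chain was requested
    if not residue_ids:
        sel = chain if chain is not None else "<first protein chain>"
        raise StructureError(f"empty selection: no Cα atoms in chain {sel} of {path}")
    label = Path(str(path)).stem
    if chosen_chain or chain:
        label = f"{label}:{chain or chosen_chain}"
    return CalphaModel(residue_ids, residue_names, np.array(coords), source_label=label)


def parse_pocket_spec(spec: str, model: CalphaModel, chain: str | None = None) -> BindingPocket:
    """Resolve a selection like ``"320-328,371-380"`` (author numbering,
    inclusive ranges, comma-separated; single numbers allowed) against a model."""
    selectors: list[int] = []
    for token in spec.split(","):
        token = token.strip()
        if not token:
            continue
        if "-" in token[1:]:  # dash after first char = range (leading '-' is a sign)
            pos = token.index("-", 1)
            lo, hi = int(token[:pos]), int(token[pos + 1 :])
        else:
            lo = hi = int(token)
        if hi < lo:
            raise StructureError(f"empty range '{token}' (end before start)")
        selectors.extend(range(lo, hi + 1))
    present = {}
    for i, (ch, num, ic) in enumerate(model.residue_ids):
        if ic == "" and (chain is None or ch == chain):
            present.setdefault(num, i)
    indices, missing = [], []
    for num in selectors:
        if num in present:
            indices.append(present[num])
        else:
            missing.append(num)
    if missing:
        raise StructureError(f"pocket residues not in model: {missing}")
    return BindingPocket(residue_selectors=selectors, resolved_indices=indices)


def _format_atom_line(serial: int, name: str, resname: str, chain: str,
                      resseq: int, icode: str, xyz: np.ndarray) -> str:
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:>5d} {name_field}{'':1s}{resname:>3s} {chain:1s}"
        f"{resseq:>4d}{icode or ' ':1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {' C':>2s}"
    )


def write_ensemble(models: Sequence[CalphaModel], path: str | Path) -> None:
    """Write conformers sharing one residue set as a multi-MODEL PDB file."""
    if not models:
        raise StructureError("no models to write")
    ref = models[0]
    for m in models[1:]:
        if m.residue_ids != ref.residue_ids:
            raise StructureError("models have inconsistent residue sets")
    buf = io.StringIO()
    for imodel, m in enumerate(models, start=1):
        buf.write(f"MODEL     {imodel:>4d}\n")
        serial = 1
        for (ch, num, ic), name, xyz in zip(m.residue_ids, m.residue_names, m.coords):
            buf.write(_format_atom_line(serial, "CA", name, ch, num, ic, xyz) + "\n")
            serial += 1
        buf.write("ENDMDL\n")
    buf.write("END\n")
    Path(path).write_text(buf.getvalue())


def read_ensemble(path: str | Path) -> list[CalphaModel]:
    """Read every MODEL block of a multi-MODEL PDB back into Cα models."""
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    out = []
    for i, _ in enumerate(structure):
        out.append(read_structure(path, model_index=i))
    return out


def read_reference_set(path: str | Path) -> list[int]:
    """Reference residue list: one author residue number per line, '#' comments."""
    numbers = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            numbers.append(int(line))
    return numbers
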