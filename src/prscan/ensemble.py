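"""Perturbation-displaced conformational ensembles.

Each conformer displaces the Cα model along the linear-response field of one
(site, direction) perturbation, scaled so the largest per-residue excursion
equals a chosen amplitude. The ensemble samples the directions a binding
event could push the backbone, for use by downstream flexible-docking
pipelines (all-atom rebuilding is left to external tools).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .enm import Compliance
from .scan import DirectionSet, perturb
from .structures import CalphaModel

__all__ = ["ConformerSpec", "generate_conformers"]


@dataclass(frozen=True)
class ConformerSpec:
    """Ensemble generation settings.

    amplitude : Å displacement of the largest-response residue in each
        conformer. The default 2.0 Å samples somewhat beyond the sub-Å
        backbone shifts typical of PDZ peptide binding.
    n_conformers : number of conformers, including the unperturbed model.
    perturbation_sites : model indices to push; None = all residues.
    seed : RNG seed for site/direction sampling past the deterministic sweep.
    """

    amplitude: float = 2.0
    n_conformers: int = 50
    perturbation_sites: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.n_conformers < 1:
            raise ValueError("n_conformers must be >= 1")


def _displacement_field(c: Compliance, site: int, direction: np.ndarray,
                        amplitude: float) -> np.ndarray:
    dr = perturb(c, site, direction).reshape(-1, 3)
    per_residue = np.linalg.norm(dr, axis=1)
    peak = per_residue.max()
    if peak <= 0:
        return np.zeros_like(dr)
    return dr * (amplitude / peak)


def generate_conformers(model: CalphaModel, c: Compliance,
                        spec: ConformerSpec | None = None,
                        min_clash_distance: float = 1.0) -> list[CalphaModel]:
    """Generate displaced conformers from PRS response fields.

    Conformer 0 is always the unperturbed model. Subsequent conformers sweep
    (site, direction) pairs deterministically over the requested sites and
    the 7 canonical directions; once the sweep is exhausted, seeded random
    sites/directions are drawn. A conformer bringing any Cα pair closer than
    ``min_clash_distance`` Å is rejected with a warning and replaced by a
    random draw.
    """
    spec = spec or ConformerSpec()
    n = model.n_residues
    sites = list(spec.perturbation_sites) if spec.perturbation_sites is not None \
        else list(range(n))
    if any(not 0 <= s < n for s in sites):
        raise IndexError("perturbation site out of range")
    directions = DirectionSet.canonical7().as_array()
    rng = np.random.default_rng(spec.seed)

    def random_pair():
        site = int(rng.integers(len(sites)))
        v = rng.normal(size=3)
        return sites[site], v / np.linalg.norm(v)

    sweep = ((s, d) for s in sites for d in directions)
    out = [model.with_coords(model.coords.copy())]
    attempts = 0
    while len(out) < spec.n_conformers:
        try:
            site, direction = next(sweep)
        except StopIteration:
            site, direction = random_pair()
        field = _displacement_field(c, site, direction, spec.amplitude)
        coords = model.coords + field
        dmat = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        np.fill_diagonal(dmat, np.inf)
        if dmat.min() < min_clash_distance:
            attempts += 1
            if attempts > 20 * spec.n_conformers:
                raise RuntimeError(
                    "could not generate a clash-free conformer; lower the amplitude")
            warnings.warn(
                f"conformer from site {site} rejected: Cα clash at "
                f"{dmat.min():.2f} Å; drawing replacement", stacklevel=2)
            sweep = iter(())  # fall through to random draws
            continue
        out.append(model.with_coords(coords))
    return out
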