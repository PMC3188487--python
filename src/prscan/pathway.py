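"""Maximum-weight intramolecular signaling pathways.

Residues that respond to a binding-site perturbation by moving along the
same line are candidates for passing the signal on. For each candidate
residue the dominant response direction under each pocket perturbation is
extracted from the 3×3 compliance block; pairs whose directions align
(mean absolute cosine ≥ cutoff, default 0.98) become edges of a
sequence-ordered DAG, and the pathway is the maximum product-weight path
through it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .enm import Compliance
from .structures import BindingPocket, CalphaModel

__all__ = [
    "DirectionalResponse",
    "OverlapGraph",
    "Pathway",
    "dominant_direction",
    "overlap_coefficient",
    "candidate_set",
    "build_overlap_graph",
    "max_weight_pathway",
]


@dataclass
class DirectionalEntry:
    """Dominant response direction of one residue to one perturbation site."""

    vector: np.ndarray | None  # unit 3-vector, canonical sign; None if no response
    spectrum: np.ndarray  # 3 non-negative values, descending

    @property
    def collectivity(self) -> float:
        total = float(self.spectrum.sum())
        return float(self.spectrum[0] / total) if total > 0 else 0.0


@dataclass
class DirectionalResponse:
    """Dominant directions for every (residue, pocket residue) pair."""

    entries: dict[tuple[int, int], DirectionalEntry] = field(default_factory=dict)
    pocket: BindingPocket | None = None

    def vector(self, residue: int, site: int) -> np.ndarray | None:
        return self.entries[(residue, site)].vector


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    """Flip sign so the first nonzero component is positive (eigenvector
    signs are arbitrary)."""
    for comp in v:
        if abs(comp) > 1e-12:
            return v if comp > 0 else -v
    return v


def dominant_direction(c: Compliance, residue: int, pocket: BindingPocket,
                       zero_tol: float = 1e-14) -> DirectionalResponse:
    """Dominant response direction of ``residue`` to each pocket perturbation.

    The 3×3 block of the compliance coupling the residue to a perturbation
    site is generally asymmetric, so it is decomposed by SVD; the left
    singular vector of the largest singular value is the direction the
    residue predominantly moves in, and the squared singular values are the
    spectrum (eigenvalues of MᵀM). A single dominant value means the residue
    moves essentially along one line.
    """
    n = c.n_residues
    if not 0 <= residue < n:
        raise IndexError(f"residue index {residue} out of range")
    out = DirectionalResponse(pocket=pocket)
    for site in pocket.resolved_indices:
        block = c.matrix[3 * residue : 3 * residue + 3, 3 * site : 3 * site + 3]
        if np.abs(block).max() <= zero_tol:
            out.entries[(residue, site)] = DirectionalEntry(
                vector=None, spectrum=np.zeros(3))
            continue
        u, s, _ = np.linalg.svd(block)
        out.entries[(residue, site)] = DirectionalEntry(
            vector=_canonical_sign(u[:, 0]), spectrum=s**2)
    return out


def overlap_coefficient(v1: np.ndarray, v2: np.ndarray) -> float:
    """|cos θ| between two dominant directions; sign-free because the
    response eigenvectors are sign-indeterminate (antiparallel counts as
    moving in line)."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    for v in (v1, v2):
        if v.shape != (3,) or not np.isclose(np.linalg.norm(v), 1.0, atol=1e-8):
            raise ValueError("overlap_coefficient expects unit 3-vectors")
    return float(min(abs(np.dot(v1, v2)), 1.0))


def candidate_set(hot: list | np.ndarray, model: CalphaModel, window: int = 3) -> list[int]:
    """Expand hot residues by sequence neighbors.

    With the default window of 3, a hot residue brings in its immediate
    sequence neighbors on both sides (e.g. hot 320 contributes 319, 320 and
    321) when those residues exist in the model. ``hot`` holds model indices
    or (chain, resnum, icode[, chi]) tuples from the χ selection.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    half = (window - 1) // 2
    indices = set()
    for h in hot:
        if isinstance(h, (int, np.integer)):
            idx = int(h)
        else:
            ch, num, ic = h[0], h[1], h[2]
            idx = model.index_of(num, chain=ch, icode=ic)
        for off in range(-half, half + 1):
            k = idx + off
            if 0 <= k < model.n_residues:
                indices.add(k)
    return sorted(indices)


@dataclass
class OverlapGraph:
    """Sequence-ordered DAG over candidate residues.

    Edges run from the lower model index to the higher one; the weight is
    the pocket-averaged overlap coefficient, kept only when ≥ cutoff.
    """

    nodes: list[int]
    edges: dict[tuple[int, int], float]
    cutoff: float
    model_ref: CalphaModel | None = None


def build_overlap_graph(candidates: list[int], directional: DirectionalResponse,
                        cutoff: float = 0.98,
                        site_combine: str = "mean",
                        model: CalphaModel | None = None,
                        max_ca_distance: float | None = None) -> OverlapGraph:
    """Link candidate pairs whose dominant directions align.

    For a pair (a < b) the pair overlap is the mean (or, with
    ``site_combine="max"``, the maximum) over pocket perturbation sites of
    the overlap coefficient between the two residues' dominant directions.
    ``max_ca_distance`` optionally restricts edges to spatially close pairs;
    by default any pair may link.
    """
    if site_combine not in ("mean", "max"):
        raise ValueError("site_combine must be 'mean' or 'max'")
    if directional.pocket is None:
        raise ValueError("directional response carries no pocket")
    sites = directional.pocket.resolved_indices
    nodes = sorted(set(int(x) for x in candidates))
    edges: dict[tuple[int, int], float] = {}
    for a, b in combinations(nodes, 2):
        if max_ca_distance is not None and model is not None:
            if np.linalg.norm(model.coords[a] - model.coords[b]) > max_ca_distance:
                continue
        vals = []
        for s in sites:
            va = directional.vector(a, s)
            vb = directional.vector(b, s)
            if va is None or vb is None:
                continue
            vals.append(overlap_coefficient(va, vb))
        if not vals:
            continue
        w = float(np.mean(vals)) if site_combine == "mean" else float(np.max(vals))
        if w >= cutoff:
            edges[(a, b)] = w
    return OverlapGraph(nodes=nodes, edges=edges, cutoff=cutoff, model_ref=model)


@dataclass
class Pathway:
    """Sequence-increasing residue chain with product weight."""

    residues: list[tuple]  # (chain, resnum, icode) in author numbering
    indices: list[int]
    edge_overlaps: list[float]
    total_weight: float
    warning: str | None = None

    def labels(self, model: CalphaModel) -> list[str]:
        return [model.label(i) for i in self.indices]


def max_weight_pathway(g: OverlapGraph) -> Pathway:
    """Exact maximum product-weight maximal path through the overlap DAG.

    A pathway runs as far as the alignment network allows: it starts at a
    node with no incoming edge and ends at a node with no outgoing edge
    (otherwise it could be extended, and extension is always taken before
    weights are compared — a lone strong edge must not beat the full chain
    it belongs to). Among these maximal source-to-sink paths, dynamic
    programming over increasing residue index finds the maximum product
    weight exactly; ties are broken toward more residues, then toward the
    smaller start residue.
    """
    if not g.nodes:
        raise ValueError("empty overlap graph")

    def resid(i: int) -> tuple:
        if g.model_ref is not None:
            return g.model_ref.residue_ids[i]
        return ("A", i + 1, "")

    if not g.edges:
        node = g.nodes[0]
        return Pathway(residues=[resid(node)], indices=[node], edge_overlaps=[],
                       total_weight=1.0,
                       warning="no edges above cutoff; single-node pathway")

    has_in = {b for (_, b) in g.edges}
    has_out = {a for (a, _) in g.edges}
    # best[v] = (weight, n_nodes, -start, predecessor) over paths source -> v
    best: dict[int, tuple[float, int, int, int | None]] = {}
    for v in g.nodes:  # ascending; every edge (a, b) has a < b
        if v not in has_in:
            best[v] = (1.0, 1, -v, None)
            continue
        cands = []
        for (a, b), w in g.edges.items():
            if b != v:
                continue
            wa, na, nsa, _ = best[a]
            cands.append((wa * w, na + 1, nsa, a))
        best[v] = max(cands, key=lambda t: t[:3])
    sinks = [v for v in g.nodes if v not in has_out and v in has_in]
    end = max(sinks, key=lambda v: best[v][:3])
    chain = [end]
    while best[chain[-1]][3] is not None:
        chain.append(best[chain[-1]][3])
    chain.reverse()
    overlaps = [g.edges[(a, b)] for a, b in zip(chain, chain[1:])]
    return Pathway(residues=[resid(i) for i in chain], indices=chain,
                   edge_overlaps=overlaps, total_weight=float(np.prod(overlaps)))
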