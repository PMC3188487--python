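"""Synthetic Cα geometries and analytic oracles.

Small deterministic structures — chains, rings, ideal α-helices, seeded
random clouds — exercise every stage of the method without any external
structure file, and a dense constrained-spring solver provides an
independent check of the linear-response displacements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .enm import EnmParameters, build_hessian
from .structures import CalphaModel

__all__ = ["FixtureSpec", "make_fixture", "analytic_response_oracle", "rigid_body_basis"]

KINDS = ("linear_chain", "ring", "ideal_helix", "random_cloud", "two_mass")


@dataclass(frozen=True)
class FixtureSpec:
    kind: str = "ideal_helix"
    n_residues: int = 20
    spacing: float = 3.8
    seed: int = 0
    box_factor: float = 1.5  # random_cloud box edge ∝ box_factor · n^(1/3) · spacing

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {KINDS}")
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")


def _model(coords: np.ndarray, label: str) -> CalphaModel:
    n = coords.shape[0]
    return CalphaModel(
        residue_ids=[("A", i + 1, "") for i in range(n)],
        residue_names=["ALA"] * n,
        coords=coords,
        source_label=label,
    )


def make_fixture(spec: FixtureSpec) -> CalphaModel:
    """Build a synthetic Cα model.

    ``linear_chain``: collinear points along x (a deliberately degenerate
    geometry with extra null modes). ``ring``: a regular polygon in the xy
    plane with edge length = spacing. ``ideal_helix``: α-helical geometry,
    3.6 residues per turn, 1.5 Å rise per residue, 2.3 Å radius (spacing is
    ignored). ``random_cloud``: seeded uniform points with pairwise
    separation ≥ spacing. ``two_mass``: two nodes on the x axis.
    """
    n, a = spec.n_residues, spec.spacing
    if spec.kind == "two_mass":
        coords = np.array([[0.0, 0.0, 0.0], [a, 0.0, 0.0]])
        return _model(coords, "two_mass")
    if spec.kind == "linear_chain":
        coords = np.column_stack([a * np.arange(n), np.zeros(n), np.zeros(n)])
        return _model(coords, f"linear_chain_{n}")
    if spec.kind == "ring":
        radius = a / (2.0 * np.sin(np.pi / n))
        theta = 2.0 * np.pi * np.arange(n) / n
        coords = np.column_stack(
            [radius * np.cos(theta), radius * np.sin(theta), np.zeros(n)])
        return _model(coords, f"ring_{n}")
    if spec.kind == "ideal_helix":
        rise, radius, per_turn = 1.5, 2.3, 3.6
        theta = 2.0 * np.pi * np.arange(n) / per_turn
        coords = np.column_stack(
            [radius * np.cos(theta), radius * np.sin(theta), rise * np.arange(n)])
        return _model(coords, f"ideal_helix_{n}")
    # random_cloud: rejection-sample inside a box scaled to hold n points
    rng = np.random.default_rng(spec.seed)
    box = a * max(2.0, spec.box_factor * n ** (1.0 / 3.0))
    pts: list[np.ndarray] = []
    for _ in range(200 * n):
        cand = rng.uniform(0.0, box, size=3)
        if all(np.linalg.norm(cand - p) >= a for p in pts):
            pts.append(cand)
            if len(pts) == n:
                break
    else:
        raise ValueError(
            f"could not place {n} points with min separation {a} in a {box:.1f} Å box")
    return _model(np.array(pts), f"random_cloud_{n}_seed{spec.seed}")


def rigid_body_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the rigid-body space (3 translations and the
    rotations about the centroid; 5 columns for collinear geometries)."""
    n = coords.shape[0]
    centered = coords - coords.mean(axis=0)
    cols = []
    for axis in range(3):
        t = np.zeros((n, 3))
        t[:, axis] = 1.0
        cols.append(t.ravel())
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = 1.0
        cols.append(np.cross(centered, e).ravel())
    basis = np.column_stack(cols)
    q, r = np.linalg.qr(basis)
    keep = np.abs(np.diag(r)) > 1e-10 * max(np.abs(np.diag(r)).max(), 1e-30)
    return q[:, keep]


def analytic_response_oracle(spec_or_model: FixtureSpec | CalphaModel,
                             site: int, direction: np.ndarray,
                             params: EnmParameters | None = None) -> np.ndarray:
    """Independent linear-response solve via a Lagrange-constrained system.

    Solves H·x = f subject to orthogonality to the rigid-body space using a
    KKT system with an explicit rigid basis — no eigendecomposition or
    pseudo-inverse, so it cross-checks the compliance route. The applied
    force is first projected off the rigid space (a net force or torque has
    no equilibrium response).
    """
    model = spec_or_model if isinstance(spec_or_model, CalphaModel) \
        else make_fixture(spec_or_model)
    h = build_hessian(model, params).matrix
    n = model.n_residues
    if not 0 <= site < n:
        raise IndexError("site out of range")
    d = np.asarray(direction, dtype=float)
    f = np.zeros(3 * n)
    f[3 * site : 3 * site + 3] = d
    basis = scipy.linalg.null_space(h, rcond=1e-10)
    if basis.shape[1] < rigid_body_basis(model.coords).shape[1]:
        raise RuntimeError("null space smaller than the rigid-body space")
    f = f - basis @ (basis.T @ f)
    k = basis.shape[1]
    kkt = np.block([[h, basis], [basis.T, np.zeros((k, k))]])
    rhs = np.concatenate([f, np.zeros(k)])
    sol = scipy.linalg.solve(kkt, rhs)
    return sol[: 3 * n]
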