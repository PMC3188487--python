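"""Cutoff-free anisotropic elastic network.

The protein is a network of Cα nodes joined by harmonic springs. Instead of
an interaction cutoff, every residue pair interacts with a spring constant
weighted by the inverse square of its separation, k_ij = c / r_ij² (c = 8 by
default), while sequence-adjacent pairs get a fixed bonded constant
γ_b = 1. The 3N×3N Hessian of this network and its Moore–Penrose
pseudo-inverse (the compliance) are the objects linear response theory needs:
ΔR = H⁺ ΔF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator

from .structures import CalphaModel

__all__ = [
    "EnmParameters",
    "Hessian",
    "Compliance",
    "ElasticNetworkModel",
    "build_hessian",
    "build_bkb_oracle",
    "compute_compliance",
    "DegenerateGeometryWarning",
]


class DegenerateGeometryWarning(UserWarning):
    """More than six null modes: the geometry is collinear or disconnected."""


@dataclass(frozen=True)
class EnmParameters:
    """Spring-constant scheme of the network.

    gamma_bonded : stiffness of sequence-adjacent (bonded) pairs; dimensionless.
    nonbonded_numerator : the constant c in k_ij = c / r_ij² for all other
        pairs, with r_ij in Å.
    min_pair_distance : Å guard below which two nodes count as coincident.
    cutoff : optional interaction cutoff in Å; ``None`` (default) lets every
        pair interact, which is the point of the distance-weighted scheme.
    """

    gamma_bonded: float = 1.0
    nonbonded_numerator: float = 8.0
    min_pair_distance: float = 1e-3
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.gamma_bonded <= 0 or self.nonbonded_numerator <= 0:
            raise ValueError("spring constants must be positive")
        if self.min_pair_distance <= 0:
            raise ValueError("min_pair_distance must be positive")


@dataclass
class Hessian:
    """3N×3N stiffness matrix of the weighted network."""

    matrix: np.ndarray
    model_ref: CalphaModel
    params_ref: EnmParameters

    @property
    def n_residues(self) -> int:
        return self.model_ref.n_residues


@dataclass
class Compliance:
    """Pseudo-inverse of the Hessian, with the null modes dropped."""

    matrix: np.ndarray
    dropped_modes: int
    tolerance_used: float
    model_ref: CalphaModel | None = None

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0] // 3


def _spring_constants(model: CalphaModel, params: EnmParameters) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise distance and spring-constant matrices (zero diagonal)."""
    coords = model.coords
    n = model.n_residues
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    off = ~np.eye(n, dtype=bool)
    too_close = off & (dist < params.min_pair_distance)
    if too_close.any():
        i, j = np.argwhere(too_close)[0]
        raise ValueError(
            f"coincident nodes: residues {model.residue_ids[i]} and "
            f"{model.residue_ids[j]} are {dist[i, j]:.2e} Å apart"
        )
    with np.errstate(divide="ignore"):
        k = np.where(off, params.nonbonded_numerator / np.where(off, dist, 1.0) ** 2, 0.0)
    if params.cutoff is not None:
        k[dist > params.cutoff] = 0.0
    bonded = model.bonded_pairs()
    if bonded.size:
        k[bonded[:, 0], bonded[:, 1]] = params.gamma_bonded
        k[bonded[:, 1], bonded[:, 0]] = params.gamma_bonded
    return dist, k


def build_hessian(model: CalphaModel, params: EnmParameters | None = None) -> Hessian:
    """Assemble the anisotropic network Hessian.

    The off-diagonal 3×3 block for pair (i, j) is −(k_ij / r_ij²)·(r_ij ⊗ r_ij);
    each diagonal block is minus the sum of its row's off-diagonal blocks, which
    enforces translation invariance exactly.
    """
    params = params or EnmParameters()
    coords = model.coords
    n = model.n_residues
    dist, k = _spring_constants(model, params)
    diff = coords[:, None, :] - coords[None, :, :]  # r_i - r_j
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(dist > 0, k / dist**2, 0.0)
    # blocks[i, j] = -scale_ij * outer(diff_ij, diff_ij)
    blocks = -scale[:, :, None, None] * (diff[:, :, :, None] * diff[:, :, None, :])
    idx = np.arange(n)
    blocks[idx, idx] = 0.0
    blocks[idx, idx] = -blocks.sum(axis=1)
    h = blocks.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)
    h = 0.5 * (h + h.T)  # kill roundoff asymmetry
    return Hessian(matrix=h, model_ref=model, params_ref=params)


def build_bkb_oracle(model: CalphaModel, params: EnmParameters | None = None) -> Hessian:
    """Independent Hessian assembly as B·K·Bᵀ.

    B is the 3N×M directional-cosine matrix over the M pairwise interactions
    and K is the M×M diagonal of spring constants. Test-only construction
    path: must equal :func:`build_hessian` to machine precision.
    """
    params = params or EnmParameters()
    coords = model.coords
    n = model.n_residues
    dist, k = _spring_constants(model, params)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if k[i, j] > 0]
    m = len(pairs)
    b = np.zeros((3 * n, m))
    kdiag = np.zeros(m)
    for col, (i, j) in enumerate(pairs):
        cosines = (coords[i] - coords[j]) / dist[i, j]
        b[3 * i : 3 * i + 3, col] = cosines
        b[3 * j : 3 * j + 3, col] = -cosines
        kdiag[col] = k[i, j]
    h = b @ np.diag(kdiag) @ b.T
    return Hessian(matrix=h, model_ref=model, params_ref=params)


def compute_compliance(h: Hessian | np.ndarray, tolerance: float = 1e-8,
                       expected_null_modes: int = 6) -> Compliance:
    """Moore–Penrose pseudo-inverse of the Hessian via symmetric eigendecomposition.

    Eigenvalues below ``tolerance`` × (largest eigenvalue) are treated as the
    rigid-body null space and dropped. A generic 3-D structure has exactly six
    (three translations, three rotations); any other count signals degenerate
    geometry and raises :class:`DegenerateGeometryWarning`.
    """
    model_ref = h.model_ref if isinstance(h, Hessian) else None
    mat = h.matrix if isinstance(h, Hessian) else np.asarray(h, dtype=float)
    if not np.allclose(mat, mat.T, rtol=1e-9, atol=1e-9 * max(1.0, np.abs(mat).max())):
        raise ValueError("Hessian must be symmetric")
    evals, evecs = scipy.linalg.eigh(mat)
    cut = tolerance * max(evals.max(), 0.0)
    null = np.abs(evals) <= cut
    dropped = int(null.sum())
    inv = np.zeros_like(evals)
    inv[~null] = 1.0 / evals[~null]
    c = (evecs * inv) @ evecs.T
    if dropped != expected_null_modes:
        warnings.warn(
            f"{dropped} null modes dropped (expected {expected_null_modes}): "
            "degenerate geometry (collinear or disconnected network)",
            DegenerateGeometryWarning,
            stacklevel=2,
        )
    return Compliance(matrix=c, dropped_modes=dropped, tolerance_used=tolerance,
                      model_ref=model_ref)


class ElasticNetworkModel(BaseEstimator):
    """Cutoff-free Cα elastic network as a fit-once estimator.

    ``fit`` takes a :class:`~prscan.structures.CalphaModel` (or a bare N×3
    coordinate array, which is treated as a single sequential chain) and
    exposes the stiffness and compliance matrices as fitted attributes.

    Parameters
    ----------
    gamma_bonded : spring constant of sequence-adjacent pairs.
    nonbonded_numerator : c in k_ij = c / r_ij² for non-bonded pairs.
    min_pair_distance : coincident-node guard in Å.
    cutoff : optional interaction cutoff in Å (default None: all pairs).
    pinv_tolerance : relative eigenvalue cutoff for the pseudo-inverse.

    Attributes
    ----------
    hessian_ : Hessian
    compliance_ : Compliance
    dropped_modes_ : int
    n_residues_ : int
    """

    def __init__(self, gamma_bonded: float = 1.0, nonbonded_numerator: float = 8.0,
                 min_pair_distance: float = 1e-3, cutoff: float | None = None,
                 pinv_tolerance: float = 1e-8):
        self.gamma_bonded = gamma_bonded
        self.nonbonded_numerator = nonbonded_numerator
        self.min_pair_distance = min_pair_distance
        self.cutoff = cutoff
        self.pinv_tolerance = pinv_tolerance

    def _params(self) -> EnmParameters:
        return EnmParameters(
            gamma_bonded=self.gamma_bonded,
            nonbonded_numerator=self.nonbonded_numerator,
            min_pair_distance=self.min_pair_distance,
            cutoff=self.cutoff,
        )

    @staticmethod
    def _as_model(X) -> CalphaModel:
        if isinstance(X, CalphaModel):
            return X
        coords = np.asarray(X, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("expected a CalphaModel or an (N, 3) coordinate array")
        n = coords.shape[0]
        return CalphaModel(
            residue_ids=[("A", i + 1, "") for i in range(n)],
            residue_names=["ALA"] * n,
            coords=coords,
            source_label="array",
        )

    def fit(self, X, y=None) -> "ElasticNetworkModel":
        model = self._as_model(X)
        self.model_ = model
        self.hessian_ = build_hessian(model, self._params())
        self.compliance_ = compute_compliance(self.hessian_, tolerance=self.pinv_tolerance)
        self.dropped_modes_ = self.compliance_.dropped_modes
        self.n_residues_ = model.n_residues
        return self

    def transform(self, forces: np.ndarray) -> np.ndarray:
        """Map force vectors (rows of shape 3N) to displacement responses."""
        f = np.atleast_2d(np.asarray(forces, dtype=float))
        if f.shape[1] != 3 * self.n_residues_:
            raise ValueError(f"force vectors must have length {3 * self.n_residues_}")
        return f @ self.compliance_.matrix.T
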