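"""Perturbation response scanning and the allosteric response ratio.

Each residue in turn is kicked with a unit force along a small set of
directions; linear response (ΔR = H⁺ΔF) gives every other residue's
displacement. The allosteric response ratio χ_j compares residue j's mean
square response to forces on the binding pocket against its mean square
response to forces anywhere, so χ_j > 1 marks residues unusually sensitive
to events at the binding site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .enm import Compliance, ElasticNetworkModel
from .structures import BindingPocket, CalphaModel, parse_pocket_spec

__all__ = [
    "DirectionSet",
    "ResponseSet",
    "ChiProfile",
    "PerturbationResponseScanner",
    "perturb",
    "scan",
    "allosteric_response_ratio",
    "select_hot_residues",
]


@dataclass(frozen=True)
class DirectionSet:
    """Unit force directions used for the scan."""

    vectors: tuple[tuple[float, float, float], ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.vectors, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("directions must be 3-vectors")
        norms = np.linalg.norm(arr, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("directions must be unit vectors")
        if len(self.labels) != len(self.vectors):
            raise ValueError("labels/vectors length mismatch")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.vectors, dtype=float)

    def __len__(self) -> int:
        return len(self.vectors)

    @classmethod
    def canonical7(cls) -> "DirectionSet":
        """The seven canonical directions: the three axes, the three face
        diagonals and the body diagonal, each normalized to unit length."""
        raw = [
            ((1, 0, 0), "x"),
            ((0, 1, 0), "y"),
            ((0, 0, 1), "z"),
            ((1, 1, 0), "xy"),
            ((1, 0, 1), "xz"),
            ((0, 1, 1), "yz"),
            ((1, 1, 1), "xyz"),
        ]
        vecs, labels = [], []
        for v, lab in raw:
            v = np.asarray(v, dtype=float)
            vecs.append(tuple(v / np.linalg.norm(v)))
            labels.append(lab)
        return cls(vectors=tuple(vecs), labels=tuple(labels))

    @classmethod
    def random(cls, n: int, seed: int) -> "DirectionSet":
        """n directions drawn uniformly on the unit sphere (seeded)."""
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        return cls(vectors=tuple(map(tuple, v)), labels=tuple(f"r{i}" for i in range(n)))


@dataclass
class ResponseSet:
    """Per-direction N×N response magnitudes A.

    ``per_direction_A[d][i, j]`` is the (squared, by default) displacement
    magnitude of residue j when residue i is pushed along direction d.
    """

    per_direction_A: list[np.ndarray]
    directions: DirectionSet
    magnitude_mode: str = "squared"
    model_ref: CalphaModel | None = None
    raw_responses: list[np.ndarray] | None = None

    @property
    def n_residues(self) -> int:
        return self.per_direction_A[0].shape[0]


@dataclass
class ChiProfile:
    """Allosteric response ratio per residue.

    ``chi[j]`` is the maximum over scan directions of the per-direction ratio
    χ_j^(d) = ⟨A_ij^(d)⟩_{i ∈ pocket} / ⟨A_ij^(d)⟩_{i ∈ all residues}.
    """

    chi: np.ndarray
    per_direction_chi: np.ndarray  # (n_directions, N)
    pocket_ref: BindingPocket
    model_ref: CalphaModel | None = None
    directions: DirectionSet | None = None
    direction_labels: tuple[str, ...] | None = None  # rows of per_direction_chi
    threshold: float = 1.0
    combine: str = "max"

    def as_dataframe(self) -> pd.DataFrame:
        n = len(self.chi)
        if self.model_ref is not None:
            chains = [rid[0] for rid in self.model_ref.residue_ids]
            nums = [rid[1] for rid in self.model_ref.residue_ids]
            names = list(self.model_ref.residue_names)
        else:
            chains, nums, names = ["A"] * n, list(range(1, n + 1)), ["ALA"] * n
        df = pd.DataFrame({"chain": chains, "resnum": nums, "resname": names,
                           "chi": self.chi, "hot": self.chi > self.threshold})
        if self.direction_labels is not None:
            labels = self.direction_labels
        elif self.directions is not None and \
                len(self.directions) == self.per_direction_chi.shape[0]:
            labels = self.directions.labels
        else:
            labels = [f"d{k}" for k in range(self.per_direction_chi.shape[0])]
        for k, lab in enumerate(labels):
            df[f"chi_{lab}"] = self.per_direction_chi[k]
        return df


def perturb(c: Compliance, residue_index: int, direction: np.ndarray,
            magnitude: float = 1.0) -> np.ndarray:
    """Displacement field ΔR (length 3N) for a force on one residue.

    The force vector is zero everywhere except the perturbed residue's three
    components, which hold ``magnitude`` times the unit direction.
    """
    n = c.n_residues
    if not 0 <= residue_index < n:
        raise IndexError(f"residue index {residue_index} out of range [0, {n})")
    d = np.asarray(direction, dtype=float)
    if d.shape != (3,) or not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
        raise ValueError("direction must be a unit 3-vector")
    f = np.zeros(3 * n)
    f[3 * residue_index : 3 * residue_index + 3] = magnitude * d
    return c.matrix @ f


def scan(c: Compliance, directions: DirectionSet | None = None,
         magnitude_mode: str = "squared", keep_raw: bool = False) -> ResponseSet:
    """Scan every residue along every direction.

    For direction d the force matrix is block-diagonal in the residue index,
    so the whole N-residue sweep is one matrix product with the compliance.
    ``magnitude_mode="squared"`` stores |ΔR_j|² (mean square fluctuation
    response, the default); ``"rms"`` stores |ΔR_j|.
    """
    if magnitude_mode not in ("squared", "rms"):
        raise ValueError("magnitude_mode must be 'squared' or 'rms'")
    directions = directions or DirectionSet.canonical7()
    n = c.n_residues
    mats, raws = [], []
    for dvec in directions.as_array():
        forces = np.zeros((3 * n, n))
        rows = np.arange(n)
        for axis in range(3):
            forces[3 * rows + axis, rows] = dvec[axis]
        resp = c.matrix @ forces  # column i = ΔR for a push on residue i
        comp = resp.reshape(n, 3, n)  # (responding residue j, axis, perturbed i)
        sq = (comp**2).sum(axis=1).T  # A[i, j]
        mats.append(sq if magnitude_mode == "squared" else np.sqrt(sq))
        if keep_raw:
            raws.append(resp.T.copy())  # (perturbed i, 3N)
    return ResponseSet(per_direction_A=mats, directions=directions,
                       magnitude_mode=magnitude_mode, model_ref=c.model_ref,
                       raw_responses=raws if keep_raw else None)


def allosteric_response_ratio(r: ResponseSet, pocket: BindingPocket,
                              threshold: float = 1.0,
                              combine: str = "max") -> ChiProfile:
    """Compute χ_j from a response set and a binding pocket.

    Per direction, χ_j^(d) is the mean response of j over pocket
    perturbations divided by its mean response over all perturbations
    (self-response included in both). ``combine="max"`` (default) takes the
    maximum over directions; ``"mean"`` averages directions first.
    """
    n = r.n_residues
    idx = np.asarray(pocket.resolved_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("empty binding pocket")
    if idx.min() < 0 or idx.max() >= n:
        raise IndexError("pocket index out of range for this response set")
    if combine not in ("max", "mean"):
        raise ValueError("combine must be 'max' or 'mean'")
    rows = []
    kept_labels = []
    for d, a in enumerate(r.per_direction_A):
        if a.max() <= 0.0:
            # the force direction lies wholly in the null space (e.g. an
            # out-of-plane push on a planar geometry): it probes nothing
            warnings.warn(
                f"direction {r.directions.labels[d]!r} produced no response; skipped",
                stacklevel=2)
            continue
        denom = a.mean(axis=0)
        if np.any(denom <= 0):
            j = int(np.argmin(denom))
            label = r.model_ref.label(j) if r.model_ref is not None else f"index {j}"
            raise ValueError(f"zero total response for residue {label}")
        rows.append(a[idx].mean(axis=0) / denom)
        kept_labels.append(r.directions.labels[d])
    if not rows:
        raise ValueError("no direction produced any response")
    per_dir = np.array(rows)
    chi = per_dir.max(axis=0) if combine == "max" else per_dir.mean(axis=0)
    return ChiProfile(chi=chi, per_direction_chi=per_dir, pocket_ref=pocket,
                      model_ref=r.model_ref, directions=r.directions,
                      direction_labels=tuple(kept_labels),
                      threshold=threshold, combine=combine)


def select_hot_residues(chi: ChiProfile, threshold: float | None = None) -> list[tuple]:
    """Residues with χ above threshold, as (chain, resnum, icode, χ) in
    descending χ order."""
    thr = chi.threshold if threshold is None else threshold
    if thr <= 0:
        raise ValueError("threshold must be positive")
    order = np.argsort(-chi.chi, kind="stable")
    out = []
    for j in order:
        if chi.chi[j] > thr:
            if chi.model_ref is not None:
                ch, num, ic = chi.model_ref.residue_ids[j]
            else:
                ch, num, ic = "A", j + 1, ""
            out.append((ch, num, ic, float(chi.chi[j])))
    return out


class PerturbationResponseScanner(BaseEstimator):
    """End-to-end PRS as an estimator.

    ``fit`` builds the elastic network and runs the directional scan;
    :meth:`chi_profile` and :meth:`hot_residues` then evaluate any binding
    pocket against the fitted responses.

    Parameters mirror :class:`~prscan.enm.ElasticNetworkModel` plus the scan
    settings (``n_random_directions=None`` uses the canonical 7-direction set).
    """

    def __init__(self, gamma_bonded: float = 1.0, nonbonded_numerator: float = 8.0,
                 cutoff: float | None = None, pinv_tolerance: float = 1e-8,
                 magnitude_mode: str = "squared", combine: str = "max",
                 threshold: float = 1.0, n_random_directions: int | None = None,
                 random_state: int = 0):
        self.gamma_bonded = gamma_bonded
        self.nonbonded_numerator = nonbonded_numerator
        self.cutoff = cutoff
        self.pinv_tolerance = pinv_tolerance
        self.magnitude_mode = magnitude_mode
        self.combine = combine
        self.threshold = threshold
        self.n_random_directions = n_random_directions
        self.random_state = random_state

    def fit(self, X, y=None) -> "PerturbationResponseScanner":
        enm = ElasticNetworkModel(
            gamma_bonded=self.gamma_bonded,
            nonbonded_numerator=self.nonbonded_numerator,
            cutoff=self.cutoff,
            pinv_tolerance=self.pinv_tolerance,
        ).fit(X)
        self.enm_ = enm
        self.model_ = enm.model_
        self.hessian_ = enm.hessian_
        self.compliance_ = enm.compliance_
        if self.n_random_directions is None:
            dirs = DirectionSet.canonical7()
        else:
            dirs = DirectionSet.random(self.n_random_directions, self.random_state)
        self.directions_ = dirs
        self.response_ = scan(enm.compliance_, dirs, magnitude_mode=self.magnitude_mode)
        self.n_residues_ = enm.n_residues_
        return self

    def _resolve_pocket(self, pocket) -> BindingPocket:
        if isinstance(pocket, BindingPocket):
            return pocket
        if isinstance(pocket, str):
            return parse_pocket_spec(pocket, self.model_)
        return BindingPocket(residue_selectors=list(pocket),
                             resolved_indices=list(pocket))

    def chi_profile(self, pocket) -> ChiProfile:
        return allosteric_response_ratio(self.response_, self._resolve_pocket(pocket),
                                         threshold=self.threshold, combine=self.combine)

    def hot_residues(self, pocket, threshold: float | None = None) -> list[tuple]:
        return select_hot_residues(self.chi_profile(pocket), threshold)
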