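"""Atomic Local Frame (ALF) descriptors and their Cartesian Jacobians.

Each atom A of the dimer carries its own local frame defined by two
reference atoms: the x-axis atom X1 and the xy-plane atom X2, chosen
deterministically from the covalent connectivity (heaviest bonded
neighbour first, ties broken by lowest global index, extended
breadth-first beyond bonded neighbours when a hydrogen has only one
neighbour).  The frame axes are

    x = (X1 - A)/|X1 - A|,  z = (X1 - A) cross (X2 - A) normalised,  y = z cross x,

and the 3N - 6 = 12 features of atom A are

    [ R(A-X1), R(A-X2), angle(X1-A-X2),
      then for each non-frame atom in ascending global index:
      r, theta in [0, pi], phi in (-pi, pi] ]

with (r, theta, phi) the spherical coordinates of the atom in A's frame.
The features are exactly invariant under global rotations and
translations, so a model built on them predicts rotation/translation
invariant energies; Cartesian forces then follow from the feature
Jacobian by the chain rule.

Jacobians are computed by complex-step forward differentiation, which is
algorithmic differentiation to machine precision (no subtractive
cancellation), through a complex-safe reimplementation of arccos/atan2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import BONDS, DimerGeometry, ELEMENTS, N_ATOMS
from .units import ATOMIC_MASSES

N_FEATURES = 3 * N_ATOMS - 6  # 12

#: 0-based positions of the azimuthal (phi) features inside a feature vector
PHI_FEATURE_INDICES: tuple[int, ...] = (5, 8, 11)

_CSTEP = 1e-100


class DegenerateFrameError(ValueError):
    """Raised when A, X1, X2 are (near-)collinear and the frame is undefined."""


@dataclass(frozen=True)
class ALFSpec:
    """The three frame atoms of one atomic local frame (0-based indices)."""

    origin_atom: int
    x_axis_atom: int
    xy_plane_atom: int

    def __post_init__(self) -> None:
        ids = (self.origin_atom, self.x_axis_atom, self.xy_plane_atom)
        if len(set(ids)) != 3 or not all(0 <= i < N_ATOMS for i in ids):
            raise ValueError(f"frame atoms must be three distinct indices in 0..5, got {ids}")

    @property
    def non_frame_atoms(self) -> tuple[int, ...]:
        frame = {self.origin_atom, self.x_axis_atom, self.xy_plane_atom}
        return tuple(i for i in range(N_ATOMS) if i not in frame)

    def to_dict(self) -> dict:
        return {"origin_atom": self.origin_atom, "x_axis_atom": self.x_axis_atom,
                "xy_plane_atom": self.xy_plane_atom}


def _neighbours() -> dict[int, list[int]]:
    nb: dict[int, list[int]] = {i: [] for i in range(N_ATOMS)}
    for i, j in BONDS:
        nb[i].append(j)
        nb[j].append(i)
    return nb


def assign_alf(atom_index: int) -> ALFSpec:
    """Deterministic frame assignment for one atom of the water dimer.

    Candidates are ranked by (atomic mass descending, global index
    ascending), first over bonded neighbours, then breadth-first over
    neighbours-of-neighbours when fewer than two candidates exist.
    """
    if not 0 <= atom_index < N_ATOMS:
        raise ValueError(f"atom index must be in 0..5, got {atom_index}")
    nb = _neighbours()

    def priority(idx: int) -> tuple[float, int]:
        return (-ATOMIC_MASSES[ELEMENTS[idx]], idx)

    candidates = sorted(nb[atom_index], key=priority)
    seen = {atom_index, *candidates}
    frontier = list(candidates)
    while len(candidates) < 2:
        if not frontier:
            raise ValueError(f"cannot build a frame for atom {atom_index}: "
                             "fewer than two reachable candidates")
        nxt = sorted({j for i in frontier for j in nb[i] if j not in seen}, key=priority)
        candidates.extend(nxt)
        seen.update(nxt)
        frontier = nxt
    return ALFSpec(atom_index, candidates[0], candidates[1])


def default_alfs() -> tuple[ALFSpec, ...]:
    """The fixed frames of all six atoms (connectivity never changes)."""
    return tuple(assign_alf(i) for i in range(N_ATOMS))


# -- complex-step-safe scalar functions --------------------------------------

def _norm(v: np.ndarray) -> np.ndarray:
    return np.sqrt((v * v).sum(-1))


def _arccos(z: np.ndarray) -> np.ndarray:
    if np.iscomplexobj(z):
        re = np.clip(z.real, -1.0, 1.0)
        return np.arccos(re) - 1j * z.imag / np.sqrt(np.clip(1.0 - re * re, 1e-16, None))
    return np.arccos(np.clip(z, -1.0, 1.0))


def _arctan2(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    if np.iscomplexobj(y) or np.iscomplexobj(x):
        yr, yi = np.real(y), np.imag(y)
        xr, xi = np.real(x), np.imag(x)
        return np.arctan2(yr, xr) + 1j * (xr * yi - yr * xi) / (xr * xr + yr * yr)
    return np.arctan2(y, x)


def _features_from_positions(pos: np.ndarray, alf: ALFSpec,
                             check: bool = True) -> np.ndarray:
    """Features for positions of shape (..., 6, 3); complex dtype supported."""
    a = pos[..., alf.origin_atom, :]
    r1 = pos[..., alf.x_axis_atom, :] - a
    r2 = pos[..., alf.xy_plane_atom, :] - a
    n1 = _norm(r1)
    n2 = _norm(r2)
    xhat = r1 / n1[..., None]
    nvec = np.cross(r1, r2)
    nn = _norm(nvec)
    if check:
        if np.any(np.real(nn) < 1e-10 * np.real(n1) * np.real(n2)):
            raise DegenerateFrameError(
                f"frame atoms {alf.origin_atom}, {alf.x_axis_atom}, "
                f"{alf.xy_plane_atom} are collinear"
            )
    zhat = nvec / nn[..., None]
    yhat = np.cross(zhat, xhat)

    ang = _arccos((r1 * r2).sum(-1) / (n1 * n2))
    feats = [n1, n2, ang]
    for j in alf.non_frame_atoms:
        d = pos[..., j, :] - a
        r = _norm(d)
        w = (d * zhat).sum(-1)
        theta = _arccos(w / r)
        phi = _arctan2((d * yhat).sum(-1), (d * xhat).sum(-1))
        feats.extend([r, theta, phi])
    return np.stack(feats, axis=-1)


@dataclass(frozen=True)
class FeatureVector:
    """The 12 ALF features of one atom."""

    values: np.ndarray
    atom_index: int
    alf: ALFSpec

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, got shape {v.shape}")
        object.__setattr__(self, "values", v)


def compute_features(g: DimerGeometry | np.ndarray, atom_index: int,
                     alf: ALFSpec | None = None) -> np.ndarray:
    """The 12-vector of ALF features of ``atom_index`` (0-based) in Angstrom
    and radians.  Accepts a geometry or an (..., 6, 3) position array."""
    alf = alf or assign_alf(atom_index)
    if alf.origin_atom != atom_index:
        raise ValueError("ALF origin does not match the requested atom")
    pos = g.positions if isinstance(g, DimerGeometry) else np.asarray(g)
    return _features_from_positions(pos, alf)


def compute_all_features(g: DimerGeometry | np.ndarray,
                         alfs: Sequence[ALFSpec] | None = None) -> np.ndarray:
    """Features of all six atoms; shape (..., 6, 12)."""
    alfs = alfs or default_alfs()
    pos = g.positions if isinstance(g, DimerGeometry) else np.asarray(g)
    return np.stack([_features_from_positions(pos, alf) for alf in alfs], axis=-2)


def feature_jacobian(g: DimerGeometry | np.ndarray, atom_index: int,
                     alf: ALFSpec | None = None) -> np.ndarray:
    """Exact (machine-precision) Jacobian d(features)/d(coordinates),
    shape (12, 18), coordinates in atom-major x,y,z order."""
    alf = alf or assign_alf(atom_index)
    pos = g.positions if isinstance(g, DimerGeometry) else np.asarray(g, dtype=float)
    if pos.shape != (N_ATOMS, 3):
        raise ValueError("feature_jacobian expects a single geometry")
    # one batched complex-step evaluation: 18 perturbed copies at once
    batch = np.broadcast_to(pos, (3 * N_ATOMS, N_ATOMS, 3)).astype(complex).copy()
    k = np.arange(3 * N_ATOMS)
    batch[k, k // 3, k % 3] += 1j * _CSTEP
    feats = _features_from_positions(batch, alf)
    return feats.imag.T / _CSTEP


def feature_jacobians(g: DimerGeometry | np.ndarray,
                      alfs: Sequence[ALFSpec] | None = None) -> np.ndarray:
    """Jacobians of all six atoms in one batched evaluation; shape (6, 12, 18)."""
    alfs = alfs or default_alfs()
    pos = g.positions if isinstance(g, DimerGeometry) else np.asarray(g, dtype=float)
    batch = np.broadcast_to(pos, (3 * N_ATOMS, N_ATOMS, 3)).astype(complex).copy()
    k = np.arange(3 * N_ATOMS)
    batch[k, k // 3, k % 3] += 1j * _CSTEP
    out = np.empty((N_ATOMS, N_FEATURES, 3 * N_ATOMS))
    for a, alf in enumerate(alfs):
        out[a] = _features_from_positions(batch, alf).imag.T / _CSTEP
    return out
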