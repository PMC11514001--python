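"""Dimer geometry types, XYZ I/O, separations and Kabsch-superposition RMSD.

Every geometry in the package is a water dimer with the fixed atom ordering
O1 H2 H3 O4 H5 H6.  Atoms 1-3 form molecule A and atoms 4-6 molecule B.
The fixed ordering gives each atom a stable identity, which the per-atom
regression models rely on.  All coordinates are in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

ELEMENTS: tuple[str, ...] = ("O", "H", "H", "O", "H", "H")
N_ATOMS = 6
ATOM_LABELS: tuple[str, ...] = ("O1", "H2", "H3", "O4", "H5", "H6")

#: covalent bonds of the dimer, 0-based (O1-H2, O1-H3, O4-H5, O4-H6)
BONDS: tuple[tuple[int, int], ...] = ((0, 1), (0, 2), (3, 4), (3, 5))

#: 0-based index pairs between molecule A (atoms 0-2) and molecule B (atoms 3-5)
INTERMOLECULAR_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (i, j) for i in range(3) for j in range(3, 6)
)


class XYZFormatError(ValueError):
    """Raised for malformed XYZ input; the message names the offending line."""


@dataclass(frozen=True)
class Atom:
    """One atom of the dimer with its fixed 1-based index."""

    element: str
    index: int  # 1-based position in the O1 H2 H3 O4 H5 H6 ordering
    position: np.ndarray  # (3,) Angstrom

    def __post_init__(self) -> None:
        if self.element not in ("O", "H"):
            raise ValueError(f"element must be O or H, got {self.element!r}")
        if not 1 <= self.index <= N_ATOMS:
            raise ValueError(f"atom index must be in 1..6, got {self.index}")
        if self.element != ELEMENTS[self.index - 1]:
            raise ValueError(
                f"atom {self.index} must be {ELEMENTS[self.index - 1]}, got {self.element}"
            )
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class DimerGeometry:
    """Six ordered atoms (O1 H2 H3 O4 H5 H6); atoms 1-3 = molecule A, 4-6 = B."""

    positions: np.ndarray  # (6, 3) Angstrom
    comment: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (N_ATOMS, 3):
            raise ValueError(f"positions must have shape (6, 3), got {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("coordinates must be finite")
        diff = pos[:, None, :] - pos[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if d.min() <= 0.0:
            raise ValueError("coincident atoms: all pairwise distances must be > 0")
        object.__setattr__(self, "positions", pos)

    @property
    def atoms(self) -> tuple[Atom, ...]:
        return tuple(
            Atom(ELEMENTS[i], i + 1, self.positions[i]) for i in range(N_ATOMS)
        )

    @classmethod
    def from_atoms(cls, atoms: Sequence[Atom], comment: str = "") -> "DimerGeometry":
        if len(atoms) != N_ATOMS:
            raise ValueError(f"expected 6 atoms, got {len(atoms)}")
        return cls(np.stack([a.position for a in atoms]), comment=comment)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "DimerGeometry":
        """Return a rigidly moved copy: ``R @ x + t`` per atom."""
        pos = self.positions
        if rotation is not None:
            pos = pos @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            pos = pos + np.asarray(translation, dtype=float)
        return DimerGeometry(pos, comment=self.comment)


@dataclass(frozen=True)
class StructurePair:
    """Reference/candidate pair for superposition; element sequences must match."""

    reference: DimerGeometry
    candidate: DimerGeometry


def read_xyz(path: str | Path) -> list[DimerGeometry]:
    """Read a (multi-frame) XYZ file of water dimers.

    Each frame must contain exactly six atom lines in the fixed
    O1 H2 H3 O4 H5 H6 element order.  Malformed input raises
    :class:`XYZFormatError` naming the 1-based line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    geometries: list[DimerGeometry] = []
    i = 0
    while i < len(lines):
        if lines[i].strip() == "" and all(l.strip() == "" for l in lines[i:]):
            break  # trailing blank lines
        try:
            count = int(lines[i].strip())
        except ValueError:
            raise XYZFormatError(
                f"{path}, line {i + 1}: malformed atom-count line {lines[i]!r}"
            ) from None
        if count != N_ATOMS:
            raise XYZFormatError(
                f"{path}, line {i + 1}: expected 6 atoms per frame, got {count}"
            )
        if i + 1 >= len(lines):
            raise XYZFormatError(f"{path}, line {i + 2}: missing comment line")
        comment = lines[i + 1]
        pos = np.empty((N_ATOMS, 3))
        for k in range(N_ATOMS):
            ln = i + 2 + k
            if ln >= len(lines):
                raise XYZFormatError(f"{path}, line {ln + 1}: truncated frame")
            parts = lines[ln].split()
            if len(parts) < 4:
                raise XYZFormatError(
                    f"{path}, line {ln + 1}: expected 'element x y z', got {lines[ln]!r}"
                )
            el = parts[0].capitalize()
            if el != ELEMENTS[k]:
                raise XYZFormatError(
                    f"{path}, line {ln + 1}: atom {k + 1} must be {ELEMENTS[k]} "
                    f"(fixed O1 H2 H3 O4 H5 H6 ordering), got {parts[0]!r}"
                )
            try:
                pos[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise XYZFormatError(
                    f"{path}, line {ln + 1}: non-numeric coordinate in {lines[ln]!r}"
                ) from None
        geometries.append(DimerGeometry(pos, comment=comment))
        i += 2 + N_ATOMS
    return geometries


def write_xyz(geometries: Iterable[DimerGeometry], path: str | Path) -> None:
    """Write geometries as multi-frame XYZ with 15 significant digits."""
    path = Path(path)
    with path.open("w") as fh:
        for g in geometries:
            fh.write(f"{N_ATOMS}\n")
            fh.write(f"{g.comment}\n")
            for el, (x, y, z) in zip(ELEMENTS, g.positions):
                fh.write(f"{el} {x:.15g} {y:.15g} {z:.15g}\n")


def _pair_distances(pos: np.ndarray, pairs: Sequence[tuple[int, int]]) -> np.ndarray:
    idx = np.asarray(pairs)
    diff = pos[idx[:, 0]] - pos[idx[:, 1]]
    return np.sqrt((diff**2).sum(-1))


def min_separation(g: DimerGeometry, mode: str = "OO") -> float:
    """Intermolecular separation of the dimer.

    mode 'OO'  -> |O1-O4|;
    mode 'OH'  -> min over the four intermolecular O...H pairs;
    mode 'any' -> min over all nine intermolecular atom pairs.
    """
    pos = g.positions
    if mode == "OO":
        return float(np.linalg.norm(pos[0] - pos[3]))
    if mode == "OH":
        pairs = [(0, 4), (0, 5), (3, 1), (3, 2)]
        return float(_pair_distances(pos, pairs).min())
    if mode == "any":
        return float(_pair_distances(pos, INTERMOLECULAR_PAIRS).min())
    raise ValueError(f"mode must be 'OO', 'OH' or 'any', got {mode!r}")


def superpose(reference: np.ndarray, candidate: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Optimal proper-rotation superposition of two point sets.

    Returns ``(rmsd, rotation, translation)`` minimising
    ``|| reference - (candidate @ R.T + t) ||`` in the least-squares sense.
    Reflections are excluded: only physical rigid motions are considered.
    """
    ref = np.asarray(reference, dtype=float)
    cand = np.asarray(candidate, dtype=float)
    if ref.shape != cand.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("point sets must share shape (n, 3)")
    ref_c = ref - ref.mean(0)
    cand_c = cand - cand.mean(0)
    rot, _ = Rotation.align_vectors(ref_c, cand_c)
    R = rot.as_matrix()
    t = ref.mean(0) - rot.apply(cand.mean(0))
    # recompute the RMSD from the aligned coordinates: the SVD residual
    # loses ~8 digits to cancellation for near-identical structures
    aligned = cand @ R.T + t
    rmsd = float(np.sqrt(((ref - aligned) ** 2).sum() / ref.shape[0]))
    return rmsd, R, t


def kabsch_rmsd(pair: StructurePair) -> float:
    """Minimum RMSD (A) of the candidate onto the reference over all proper
    rotations and translations (unweighted Kabsch superposition)."""
    rmsd, _, _ = superpose(pair.reference.positions, pair.candidate.positions)
    return rmsd
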