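"""Synthetic water-dimer dataset generation (WD24-style).

The sampler draws dimer configurations uniformly and fully over the
configuration space: each monomer gets independently sampled internal
coordinates (uniform OH bond lengths and HOH angle) and an orientation
drawn uniformly from the rotation group, and the two molecules are placed
at a separation drawn uniformly from a configured range along a uniformly
random direction.  Because both monomers are sampled identically, either
molecule can act as hydrogen-bond donor or acceptor with equal probability.

Randomness is counter-based: candidate ``k`` of a run is generated from a
Philox substream keyed by ``(seed, k)``, so the dataset is bitwise
reproducible and independent of batching or parallel evaluation order.
Geometries failing the contact/bond filter are discarded and the counter
advances until the requested number of accepted geometries exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import BONDS, DimerGeometry, min_separation, write_xyz

#: equilibrium-like monomer internal coordinates (A, degrees)
OH_EQUILIBRIUM = 0.9572
HOH_EQUILIBRIUM_DEG = 104.52


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling ranges and filter settings for dataset generation.

    Defaults are the WD24-style study conditions: oxygen-oxygen separations
    uniform on [2.0, 5.5] A, monomer OH bonds uniform on [0.85, 1.10] A and
    HOH angles uniform on [95, 115] degrees (generous brackets of thermal
    distortion at 298 K), and a 1.4 A minimum intermolecular contact.
    """

    n_geometries: int = 1000
    separation_range: tuple[float, float] = (2.0, 5.5)
    separation_mode: str = "OO"  # 'OO' or 'any'
    oh_range: tuple[float, float] = (0.85, 1.10)
    hoh_range_deg: tuple[float, float] = (95.0, 115.0)
    min_contact: float = 1.4
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.separation_range
        if not 0 < lo < hi:
            raise ValueError("separation_range must satisfy 0 < min < max")
        if self.separation_mode not in ("OO", "any"):
            raise ValueError("separation_mode must be 'OO' or 'any'")
        if not self.oh_range[0] <= OH_EQUILIBRIUM <= self.oh_range[1]:
            raise ValueError("oh_range must contain the equilibrium bond length")
        if not self.hoh_range_deg[0] <= HOH_EQUILIBRIUM_DEG <= self.hoh_range_deg[1]:
            raise ValueError("hoh_range_deg must contain the equilibrium angle")
        if self.n_geometries < 0:
            raise ValueError("n_geometries must be non-negative")


def wd24_config(seed: int = 0, n_geometries: int = 100_000) -> GeneratorConfig:
    """The WD24 preset: 100,000 dimers, separations uniform on [2.0, 5.5] A."""
    return GeneratorConfig(n_geometries=n_geometries, seed=seed)


@dataclass(frozen=True)
class Dataset:
    """An ordered collection of dimer geometries plus its provenance."""

    geometries: tuple[DimerGeometry, ...]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.geometries)

    def __iter__(self):
        return iter(self.geometries)

    def __getitem__(self, i):
        return self.geometries[i]

    def to_array(self) -> np.ndarray:
        """Positions as an (n, 6, 3) array."""
        return np.stack([g.positions for g in self.geometries]) if self.geometries \
            else np.empty((0, 6, 3))


@dataclass(frozen=True)
class SplitDataset:
    train: Dataset
    test: Dataset


def _substream(seed: int, counter: int) -> np.random.Generator:
    # Philox is counter-based: a disjoint, reproducible stream per candidate.
    return np.random.Generator(np.random.Philox(key=seed, counter=counter << 8))


def _quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q / np.linalg.norm(q)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Rotation matrix uniform over SO(3) (normalised-Gaussian quaternion)."""
    q = rng.normal(size=4)
    return _quaternion_to_matrix(q)


def sample_monomer(rng: np.random.Generator, config: GeneratorConfig) -> np.ndarray:
    """Sample one water monomer in its canonical local frame, O at the origin.

    The two OH bond lengths are independent uniform draws from the bond
    range and the HOH angle a uniform draw from the angle range.  H1 lies
    on the +x axis; H2 lies in the xy-plane.  Returns a (3, 3) array
    ordered O, H, H.
    """
    r1 = rng.uniform(*config.oh_range)
    r2 = rng.uniform(*config.oh_range)
    theta = np.deg2rad(rng.uniform(*config.hoh_range_deg))
    return np.array([
        [0.0, 0.0, 0.0],
        [r1, 0.0, 0.0],
        [r2 * np.cos(theta), r2 * np.sin(theta), 0.0],
    ])


def sample_dimer(rng: np.random.Generator, config: GeneratorConfig) -> DimerGeometry:
    """Sample one dimer: two independent monomers with uniform orientations,
    placed at a separation uniform on ``separation_range`` along a uniformly
    random direction.

    In mode 'OO' the separation is |O1-O4| exactly; in mode 'any' the second
    molecule is placed so the closest intermolecular contact equals the drawn
    value.
    """
    mono_a = sample_monomer(rng, config) @ random_rotation(rng).T
    mono_b = sample_monomer(rng, config) @ random_rotation(rng).T
    s = rng.uniform(*config.separation_range)
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    if config.separation_mode == "OO":
        offset = s * u
    else:
        # place B so its closest approach to A along u equals s: shift until
        # min over intermolecular pairs of |a_i - (b_j + c u)| = s by 1D solve
        offset = _offset_for_any_mode(mono_a, mono_b, u, s)
    pos = np.vstack([mono_a, mono_b + offset])
    return DimerGeometry(pos)


def _offset_for_any_mode(mono_a: np.ndarray, mono_b: np.ndarray,
                         u: np.ndarray, s: float) -> np.ndarray:
    from scipy.optimize import brentq

    def closest(c: float) -> float:
        d = mono_a[:, None, :] - (mono_b[None, :, :] + c * u)
        return float(np.sqrt((d**2).sum(-1)).min())

    lo, hi = 0.0, 50.0
    f = lambda c: closest(c) - s
    if f(lo) > 0:  # already farther than s at zero offset: move inwards is impossible
        return s * u
    return brentq(f, lo, hi, xtol=1e-10) * u


def filter_geometry(g: DimerGeometry, config: GeneratorConfig) -> tuple[bool, str | None]:
    """Accept/reject a geometry.

    Rejects when any intermolecular atom-atom distance falls below
    ``min_contact`` ('close contact') or when any intramolecular OH bond
    lies outside the configured distortion range inflated by 10%
    ('bond out of range').
    """
    if min_separation(g, "any") < config.min_contact:
        return False, "close contact"
    lo, hi = config.oh_range
    width = hi - lo
    lo_inf, hi_inf = lo - 0.1 * width, hi + 0.1 * width
    pos = g.positions
    for i, j in BONDS:
        r = float(np.linalg.norm(pos[i] - pos[j]))
        if not lo_inf <= r <= hi_inf:
            return False, "bond out of range"
    return True, None


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """Generate exactly ``config.n_geometries`` filtered dimers.

    Rejection sampling tops up until the requested count is reached; the
    candidate counter, not the accepted index, keys each substream, so the
    output is bitwise reproducible from the seed.  Aborts if the rejection
    rate exceeds 99% after a warm-up.
    """
    accepted: list[DimerGeometry] = []
    k = 0
    n = config.n_geometries
    while len(accepted) < n:
        rng = _substream(config.seed, k)
        g = sample_dimer(rng, config)
        ok, _ = filter_geometry(g, config)
        if ok:
            accepted.append(g)
        k += 1
        if k >= 1000 and len(accepted) < 0.01 * k:
            raise RuntimeError(
                f"filter rejected {k - len(accepted)}/{k} candidates (>99%); "
                "check min_contact against the separation range"
            )
    provenance = {"config": asdict(config), "n_candidates": k}
    return Dataset(tuple(accepted), provenance)


def split_dataset(d: Dataset, n_train: int, n_test: int, seed: int) -> SplitDataset:
    """Uniform random disjoint train/test partition, reproducible from seed."""
    if n_train + n_test > len(d):
        raise ValueError(
            f"cannot split {len(d)} geometries into {n_train} + {n_test}"
        )
    rng = np.random.Generator(np.random.Philox(key=seed, counter=1 << 64))
    perm = rng.permutation(len(d))
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:n_train + n_test])
    prov = dict(d.provenance)
    prov["split_seed"] = seed
    train = Dataset(tuple(d.geometries[i] for i in train_idx), {**prov, "role": "train"})
    test = Dataset(tuple(d.geometries[i] for i in test_idx), {**prov, "role": "test"})
    return SplitDataset(train=train, test=test)


def distance_distribution(d: Dataset, mode: str = "OO",
                          bins: int = 35) -> tuple[np.ndarray, np.ndarray]:
    """Histogram (edges, counts) of intermolecular separations of a dataset."""
    if len(d) == 0:
        raise ValueError("dataset is empty")
    values = np.array([min_separation(g, mode) for g in d])
    counts, edges = np.histogram(values, bins=bins)
    return edges, counts


def is_molecule_a_donor(g: DimerGeometry) -> bool:
    """Geometric donor criterion: the shortest intermolecular O...H contact
    involves one of molecule A's hydrogens."""
    pos = g.positions
    a_donates = min(np.linalg.norm(pos[3] - pos[1]), np.linalg.norm(pos[3] - pos[2]))
    b_donates = min(np.linalg.norm(pos[0] - pos[4]), np.linalg.norm(pos[0] - pos[5]))
    return bool(a_donates < b_donates)


def save_dataset(d: Dataset, xyz_path: str | Path,
                 provenance_path: str | Path | None = None) -> None:
    """Write the geometries as multi-frame XYZ plus a key-value sidecar."""
    write_xyz(d.geometries, xyz_path)
    if provenance_path is not None:
        lines = _flatten_provenance(d.provenance)
        Path(provenance_path).write_text("".join(f"{k} = {v}\n" for k, v in lines))


def _flatten_provenance(prov: dict, prefix: str = "") -> list[tuple[str, object]]:
    out: list[tuple[str, object]] = []
    for k, v in prov.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.extend(_flatten_provenance(v, prefix=f"{key}."))
        else:
            out.append((key, v))
    return out
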