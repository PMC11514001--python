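"""Orchestration helpers: featurize labeled datasets, train the six atomic
models, and persist/load a complete dimer potential."""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .alf import default_alfs, compute_all_features
from .engine import DimerPotential
from .geometry import ATOM_LABELS, N_ATOMS
from .gpr import TrainingConfig, load_model, save_model, train_atomic_model
from .oracle import LabeledGeometry


def featurize_labeled(labeled: Sequence[LabeledGeometry]) -> tuple[np.ndarray, np.ndarray]:
    """ALF features (n, 6, 12) and atomic energies (n, 6) of a labeled set."""
    if len(labeled) == 0:
        raise ValueError("labeled dataset is empty")
    pos = np.stack([lg.geometry.positions for lg in labeled])
    feats = compute_all_features(pos, default_alfs())
    energies = np.stack([lg.atomic_energies for lg in labeled])
    return feats, energies


def train_dimer_potential(labeled: Sequence[LabeledGeometry],
                          config: TrainingConfig | None = None,
                          verbose: bool = False) -> DimerPotential:
    """Train one GP per atom on its IQA-style surrogate energies and
    assemble the six models into a dimer potential.

    Each atom gets its own seed substream (derived from the config seed
    and the atom index) so the per-atom searches are independent yet
    reproducible.
    """
    config = config or TrainingConfig()
    feats, energies = featurize_labeled(labeled)
    alfs = default_alfs()
    models = []
    for a in range(N_ATOMS):
        cfg = replace(config, seed=(config.seed * N_ATOMS + a) % (2**31))
        model = train_atomic_model(feats[:, a, :], energies[:, a], cfg,
                                   atom_index=a, alf=alfs[a])
        if verbose:
            print(f"  {ATOM_LABELS[a]}: n={model.n_train} "
                  f"lml={model.info['lml']:.2f} "
                  f"prior_mean={model.hyperparameters.prior_mean:.3f} kJ/mol")
        models.append(model)
    return DimerPotential(tuple(models))


def save_potential(potential: DimerPotential, directory: str | Path) -> None:
    """Persist the six atomic models as <dir>/atom_<label>.npz."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for m in potential.atomic_models:
        save_model(m, directory / f"atom_{ATOM_LABELS[m.atom_index]}.npz")


def load_potential(directory: str | Path) -> DimerPotential:
    directory = Path(directory)
    models = []
    for label in ATOM_LABELS:
        path = directory / f"atom_{label}.npz"
        if not path.exists():
            raise FileNotFoundError(f"missing atomic model file {path}")
        models.append(load_model(path))
    return DimerPotential(tuple(models))
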