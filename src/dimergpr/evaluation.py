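"""Accuracy metrics: S-curves, MAEs, fraction-within-threshold and
per-component force error tables."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ATOM_LABELS
from .units import CHEMICAL_ACCURACY_KJ_MOL


@dataclass(frozen=True)
class SCurve:
    """Sorted absolute errors against cumulative percentiles (0, 100]."""

    errors: np.ndarray       # non-decreasing
    percentiles: np.ndarray  # strictly increasing, ends at 100


def s_curve(errors) -> SCurve:
    """Cumulative error curve: the percentile of the i-th smallest error is
    100 (i+1) / n, so tied errors share the highest applicable percentile
    ('geometries displaying this error or less')."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("need at least one error value")
    if np.any(e < 0):
        raise ValueError("absolute errors must be non-negative")
    e = np.sort(e)
    pct = 100.0 * np.arange(1, e.size + 1) / e.size
    return SCurve(e, pct)


def mae(predictions, references) -> float:
    """Mean absolute error."""
    p = np.asarray(predictions, dtype=float)
    r = np.asarray(references, dtype=float)
    if p.shape != r.shape or p.size == 0:
        raise ValueError("predictions and references must share a non-empty shape")
    return float(np.abs(p - r).mean())


def fraction_within(errors, threshold: float) -> float:
    """Percentage of absolute errors at or below ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    e = np.asarray(errors, dtype=float)
    return float(100.0 * np.count_nonzero(e <= threshold) / e.size)


def force_component_report(predicted: np.ndarray, reference: np.ndarray) -> pd.DataFrame:
    """Per-atom, per-Cartesian-component force MAE table (6 x 3), averaged
    over frames; rows labelled O1..H6, columns x, y, z."""
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape or p.ndim != 3 or p.shape[1:] != (6, 3):
        raise ValueError("expected matching (n_frames, 6, 3) force arrays")
    table = np.abs(p - r).mean(0)
    return pd.DataFrame(table, index=list(ATOM_LABELS), columns=["x", "y", "z"])


@dataclass(frozen=True)
class ErrorReport:
    """Summary statistics of one prediction run."""

    per_atom_mae: dict[str, float]
    total_energy_mae: float
    fraction_within_1kj: float
    fraction_within_chemical_accuracy: float
    max_error: float

    def to_frame(self) -> pd.DataFrame:
        rows = {f"mae_{k}": v for k, v in self.per_atom_mae.items()}
        rows.update({
            "mae_total": self.total_energy_mae,
            "pct_within_1_kj_mol": self.fraction_within_1kj,
            "pct_within_chemical_accuracy": self.fraction_within_chemical_accuracy,
            "max_error": self.max_error,
        })
        return pd.DataFrame({"value": rows})


def error_report(predicted_atomic: np.ndarray, reference_atomic: np.ndarray) -> ErrorReport:
    """Build the summary report from (n, 6) predicted and reference atomic
    energies; totals are the per-geometry sums."""
    p = np.asarray(predicted_atomic, dtype=float)
    r = np.asarray(reference_atomic, dtype=float)
    if p.shape != r.shape or p.ndim != 2 or p.shape[1] != 6:
        raise ValueError("expected matching (n, 6) atomic-energy arrays")
    per_atom = {ATOM_LABELS[a]: mae(p[:, a], r[:, a]) for a in range(6)}
    total_err = np.abs(p.sum(1) - r.sum(1))
    return ErrorReport(
        per_atom_mae=per_atom,
        total_energy_mae=float(total_err.mean()),
        fraction_within_1kj=fraction_within(total_err, 1.0),
        fraction_within_chemical_accuracy=fraction_within(
            total_err, CHEMICAL_ACCURACY_KJ_MOL),
        max_error=float(total_err.max()),
    )


def save_s_curve_plot(curve: SCurve, path: str | Path, title: str = "") -> None:
    """Optional S-curve plot (log-x absolute error vs cumulative percentile)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(np.maximum(curve.errors, 1e-12), curve.percentiles)
    ax.set_xscale("log")
    ax.set_xlabel("absolute error (kJ/mol)")
    ax.set_ylabel("percentile (%)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
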