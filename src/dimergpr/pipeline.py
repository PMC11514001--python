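"""End-to-end pipeline: generate -> label -> train -> evaluate, with stage
caching keyed by content hashes and a single resolved-config snapshot.

The run configuration is a small hierarchical mapping (YAML on disk) with
one section per stage.  Unknown keys are rejected so typos cannot silently
fall back to defaults.  One global seed fans out to per-stage substreams,
so an individual stage re-run reproduces its part of a full run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .evaluation import error_report, s_curve
from .generator import GeneratorConfig, generate_dataset, save_dataset, split_dataset
from .gpr import TrainingConfig
from .oracle import (
    OraclePotentialSpec,
    label_dataset,
    load_labeled_dataset,
    save_labeled_dataset,
)
from .training import load_potential, save_potential, train_dimer_potential

logger = logging.getLogger("dimergpr")

#: stage name -> seed-substream offset
_STAGE_OFFSETS = {"generate": 1, "split": 2, "train": 3}

_KNOWN_KEYS: dict[str, set[str]] = {
    "": {"seed", "output_dir", "generator", "oracle", "training", "evaluation"},
    "generator": {"n_geometries", "separation_range", "separation_mode",
                  "oh_range", "hoh_range_deg", "min_contact"},
    "oracle": {"bond_k", "bond_r0", "angle_k", "angle_theta0", "charge_o",
               "charge_h", "lj_epsilon", "lj_sigma", "coulomb_k"},
    "training": {"n_train", "n_test", "max_iter", "n_restarts", "restart_scale",
                 "jitter", "block_size", "hyperopt_subset", "optimize_noise",
                 "noise_floor"},
    "evaluation": {"thresholds"},
}


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    output_dir: str = "dimergpr_run"
    generator: dict = field(default_factory=dict)
    oracle: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, raw: dict[str, Any]) -> "RunConfig":
        _check_keys("", raw)
        for section in ("generator", "oracle", "training", "evaluation"):
            _check_keys(section, raw.get(section, {}))
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_mapping(raw)

    def resolved(self) -> dict:
        gen = self.generator_config()
        return _plain({
            "seed": self.seed,
            "output_dir": self.output_dir,
            "generator": {**asdict(gen)},
            "oracle": self.oracle_spec().to_dict(),
            "training": {"n_train": self.n_train, "n_test": self.n_test,
                         **{k: getattr(self.training_config(), k)
                            for k in ("max_iter", "n_restarts", "restart_scale",
                                      "jitter", "block_size", "hyperopt_subset",
                                      "optimize_noise", "noise_floor", "seed")}},
            "evaluation": {"thresholds": self.thresholds},
        })

    def generator_config(self) -> GeneratorConfig:
        kw = dict(self.generator)
        for key in ("separation_range", "oh_range", "hoh_range_deg"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return GeneratorConfig(seed=self.seed * 8 + _STAGE_OFFSETS["generate"], **kw)

    def oracle_spec(self) -> OraclePotentialSpec:
        return OraclePotentialSpec(**self.oracle)

    @property
    def n_train(self) -> int:
        return int(self.training.get("n_train",
                                     max(2, int(0.6 * self.generator_config().n_geometries))))

    @property
    def n_test(self) -> int:
        return int(self.training.get("n_test",
                                     max(1, int(0.2 * self.generator_config().n_geometries))))

    def training_config(self) -> TrainingConfig:
        kw = {k: v for k, v in self.training.items() if k not in ("n_train", "n_test")}
        return TrainingConfig(seed=self.seed * 8 + _STAGE_OFFSETS["train"], **kw)

    @property
    def thresholds(self) -> list[float]:
        return list(self.evaluation.get("thresholds", [1.0, 4.184]))


def _plain(obj: Any):
    """Recursively convert numpy scalars and tuples to YAML-safe builtins."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _check_keys(section: str, mapping: dict) -> None:
    if not isinstance(mapping, dict):
        raise ValueError(f"config section {section or '<root>'} must be a mapping")
    unknown = set(mapping) - _KNOWN_KEYS[section]
    if unknown:
        raise ValueError(
            f"unknown config key(s) in {section or '<root>'}: {sorted(unknown)}")


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_obj(obj: Any) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


class _StageCache:
    """Content-hash stage cache: a stage re-runs only when its key (config
    slice + upstream artifact hashes) changed."""

    def __init__(self, outdir: Path):
        self.path = outdir / "stage_manifest.json"
        self.manifest: dict[str, str] = {}
        if self.path.exists():
            self.manifest = json.loads(self.path.read_text())

    def fresh(self, stage: str, key: str, artifacts: list[Path]) -> bool:
        return (self.manifest.get(stage) == key
                and all(p.exists() for p in artifacts))

    def record(self, stage: str, key: str) -> None:
        self.manifest[stage] = key
        self.path.write_text(json.dumps(self.manifest, indent=1))


def run_pipeline(config: RunConfig, verbose: bool = True) -> dict:
    """Run generate -> label -> train -> evaluate and return the summary.

    Artifacts land under ``config.output_dir``: the dataset (XYZ +
    provenance), labeled train/test CSVs, six atomic model files, the
    resolved-config snapshot, and ``summary.json`` with per-atom MAEs,
    total-energy S-curve samples, and threshold fractions.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s [%(name)s] %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    if verbose and not any(isinstance(h, logging.StreamHandler)
                           and not isinstance(h, logging.FileHandler)
                           for h in logger.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("[%(name)s:%(levelname)s] %(message)s"))
        logger.addHandler(sh)

    try:
        (outdir / "resolved_config.yaml").write_text(
            yaml.safe_dump(config.resolved(), sort_keys=False))
        cache = _StageCache(outdir)

        # -- generate ---------------------------------------------------
        gen_cfg = config.generator_config()
        xyz_path = outdir / "dataset.xyz"
        prov_path = outdir / "dataset.provenance.txt"
        gen_key = _hash_obj(asdict(gen_cfg))
        if not cache.fresh("generate", gen_key, [xyz_path, prov_path]):
            logger.info("stage generate: sampling %d dimers", gen_cfg.n_geometries)
            dataset = generate_dataset(gen_cfg)
            save_dataset(dataset, xyz_path, prov_path)
            cache.record("generate", gen_key)
        else:
            logger.info("stage generate: cached")
            from .generator import Dataset
            from .geometry import read_xyz

            dataset = Dataset(tuple(read_xyz(xyz_path)),
                              {"config": asdict(gen_cfg)})

        # -- label + split ----------------------------------------------
        spec = config.oracle_spec()
        train_csv = outdir / "train_labeled.csv"
        test_csv = outdir / "test_labeled.csv"
        label_key = _hash_obj({"oracle": spec.to_dict(), "upstream": gen_key,
                               "n_train": config.n_train, "n_test": config.n_test,
                               "seed": config.seed})
        if not cache.fresh("label", label_key, [train_csv, test_csv]):
            logger.info("stage label: surrogate labels + %d/%d split",
                        config.n_train, config.n_test)
            split = split_dataset(dataset, config.n_train, config.n_test,
                                  seed=config.seed * 8 + _STAGE_OFFSETS["split"])
            save_labeled_dataset(label_dataset(split.train, spec), train_csv)
            save_labeled_dataset(label_dataset(split.test, spec), test_csv)
            cache.record("label", label_key)
        else:
            logger.info("stage label: cached")
        train_labeled = load_labeled_dataset(train_csv)
        test_labeled = load_labeled_dataset(test_csv)

        # -- train -------------------------------------------------------
        tr_cfg = config.training_config()
        model_dir = outdir / "models"
        train_key = _hash_obj({"training": str(tr_cfg), "upstream": label_key,
                               "data": _hash_file(train_csv)})
        model_files = [model_dir / f"atom_{lab}.npz"
                       for lab in ("O1", "H2", "H3", "O4", "H5", "H6")]
        if not cache.fresh("train", train_key, model_files):
            logger.info("stage train: fitting six atomic models on %d points",
                        len(train_labeled))
            potential = train_dimer_potential(train_labeled, tr_cfg)
            save_potential(potential, model_dir)
            cache.record("train", train_key)
        else:
            logger.info("stage train: cached")
            potential = load_potential(model_dir)

        # -- evaluate ----------------------------------------------------
        logger.info("stage evaluate: %d test geometries", len(test_labeled))
        test_pos = np.stack([lg.geometry.positions for lg in test_labeled])
        pred_atomic = potential.atomic_energies(test_pos)
        ref_atomic = np.stack([lg.atomic_energies for lg in test_labeled])
        report = error_report(pred_atomic, ref_atomic)
        total_err = np.abs(pred_atomic.sum(1) - ref_atomic.sum(1))
        curve = s_curve(total_err)
        summary = {
            "n_train": len(train_labeled),
            "n_test": len(test_labeled),
            "per_atom_mae_kj_mol": report.per_atom_mae,
            "total_energy_mae_kj_mol": report.total_energy_mae,
            "pct_within_1_kj_mol": report.fraction_within_1kj,
            "pct_within_chemical_accuracy": report.fraction_within_chemical_accuracy,
            "max_total_error_kj_mol": report.max_error,
            "s_curve_sample": {
                "errors_kj_mol": curve.errors[:: max(1, len(total_err) // 50)].tolist(),
                "percentiles": curve.percentiles[:: max(1, len(total_err) // 50)].tolist(),
            },
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
        logger.info("pipeline complete: total-energy MAE %.3f kJ/mol, "
                    "%.1f%% within chemical accuracy",
                    report.total_energy_mae,
                    report.fraction_within_chemical_accuracy)
        return summary
    except Exception as exc:
        logger.error("pipeline halted: %s (log: %s)", exc, log_path)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
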