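"""Timeseries container, delimited-text I/O, config handling and pipelines.

Timeseries files are delimited text with a header row of node labels and one
column per node.  Run results are stored in a single hierarchical JSON file
per run; every artifact records the config hash and seed that produced it.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, ValidationError

__all__ = [
    "Timeseries",
    "load_timeseries",
    "save_timeseries",
    "load_config",
    "config_hash",
    "save_results",
    "load_results",
    "run_pipeline",
]

MIN_ROWS = 64


@dataclass(frozen=True)
class Timeseries:
    """Multi-region timeseries: (n_samples, n_nodes) values plus metadata."""

    values: np.ndarray
    sampling_interval: float
    node_labels: tuple = field(default=None)

    def __post_init__(self):
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v)):
            bad = np.argwhere(~np.isfinite(v))[0]
            raise ValidationError(
                f"non-finite value at row {bad[0]}, column {bad[1]}"
            )
        if self.sampling_interval <= 0:
            raise ValidationError("sampling interval must be positive")
        if self.node_labels is None:
            object.__setattr__(
                self, "node_labels",
                tuple(f"node{i}" for i in range(v.shape[1])),
            )
        elif len(self.node_labels) != v.shape[1]:
            raise ValidationError("node label count does not match columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.node_labels))


def load_timeseries(path, sampling_interval: float, delimiter: str = "\t") -> Timeseries:
    """Read a delimited-text timeseries (header row of node labels)."""
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    arr = df.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                raise ValidationError(
                    f"non-numeric cell at row {int(bad.idxmax())}, column '{col}'"
                )
        arr = df.apply(pd.to_numeric).to_numpy()
    if np.isnan(arr).any():
        i, j = np.argwhere(np.isnan(arr))[0]
        raise ValidationError(
            f"missing/NaN value at row {i}, column '{df.columns[j]}'"
        )
    if arr.shape[0] < MIN_ROWS:
        raise ValidationError(
            f"timeseries has {arr.shape[0]} rows; need at least {MIN_ROWS}"
        )
    return Timeseries(arr, sampling_interval, tuple(df.columns))


def save_timeseries(ts: Timeseries, path, delimiter: str = "\t") -> None:
    """Write a timeseries as delimited text (header row of labels)."""
    ts.to_frame().to_csv(path, sep=delimiter, index=False, float_format="%.17g")


# -- configuration -----------------------------------------------------------

_CONFIG_SCHEMA = {
    "seed": int,
    "sampling_interval": (int, float),
    "n_samples": int,
    "n_unstable": int,
    "stable_log_decay": (int, float),
    "estimator": str,
    "n_freq": int,
    "n_lags": int,
    "stages": list,
    "timeseries": str,
    "out_dir": str,
    "m_values": list,
    "eta_grid": list,
    "mds_dimension": int,
}

_DEFAULT_CONFIG = {
    "sampling_interval": 2.0,
    "n_samples": 512,
    "n_unstable": 3,
    "stable_log_decay": 1.0,
    "estimator": "mar",
    "n_freq": 32,
    "n_lags": 32,
    "stages": ["simulate", "features", "fit"],
    "out_dir": "eigendcm_run",
    "mds_dimension": 3,
}


def load_config(path_or_dict) -> dict:
    """Load and schema-check a YAML/JSON config; fill defaults.

    Seeds are mandatory: there is no silent global random state.
    """
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    cfg = dict(_DEFAULT_CONFIG)
    cfg.update(raw)
    if "seed" not in cfg:
        raise ConfigError("config key 'seed' is required (no implicit RNG state)")
    for key, val in cfg.items():
        if key in _CONFIG_SCHEMA and not isinstance(val, _CONFIG_SCHEMA[key]):
            raise ConfigError(
                f"config key '{key}' has type {type(val).__name__}, "
                f"expected {_CONFIG_SCHEMA[key]}"
            )
    for stage in cfg["stages"]:
        if stage not in ("simulate", "features", "fit", "compare", "project"):
            raise ConfigError(f"unknown stage '{stage}' in config key 'stages'")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# -- results container -------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        if np.iscomplexobj(obj):
            return {"__complex__": True, "real": obj.real.tolist(), "imag": obj.imag.tolist()}
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_results(results: dict, path) -> None:
    """Serialise a (nested) results mapping to JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(results), fh, indent=1)


def load_results(path, expect_config_hash: str = None) -> dict:
    """Load a results JSON; warn if its config hash does not match."""
    with open(path) as fh:
        out = json.load(fh)
    if expect_config_hash is not None and out.get("config_hash") != expect_config_hash:
        warnings.warn(
            f"config hash mismatch: results carry {out.get('config_hash')}, "
            f"expected {expect_config_hash}"
        )
    return out


# -- pipeline ----------------------------------------------------------------

def run_pipeline(config) -> dict:
    """Execute the configured stages in order and write all artifacts.

    Stages: ``simulate`` (synthetic scenario), ``features`` (spectral
    features of the timeseries), ``fit`` (model inversion), ``compare``
    (model-space sweeps), ``project`` (scaling-space coordinates).  Returns
    the in-memory results bundle; artifacts are written under ``out_dir``.
    """
    import time

    from . import compare as cmp_mod
    from . import scaling as scaling_mod
    from . import simulate as sim_mod
    from .model import SpectralDCM

    cfg = load_config(config)
    chash = config_hash(cfg)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    results = {"config": cfg, "config_hash": chash, "seed": cfg["seed"], "log": []}
    ts = None
    model = None
    fitres = None

    def log(stage, t0, **extra):
        results["log"].append({"stage": stage, "seconds": time.time() - t0, **extra})

    for stage in cfg["stages"]:
        t0 = time.time()
        if stage == "simulate":
            bundle = sim_mod.default_scenario(
                cfg["seed"], n_samples=cfg["n_samples"],
                sampling_interval=cfg["sampling_interval"],
            )
            ts = bundle.bold
            save_timeseries(ts, out_dir / "bold.tsv")
            results["simulate"] = {
                "jacobian_true": bundle.jacobian_true,
                "tau_true": bundle.spec.log_time_constants,
                "log_decay": bundle.spec.log_decay,
            }
            log(stage, t0)
        elif stage == "features":
            if ts is None:
                ts = load_timeseries(cfg["timeseries"], cfg["sampling_interval"])
            model = SpectralDCM(
                ts.values, ts.sampling_interval,
                n_unstable=cfg["n_unstable"],
                stable_log_decay=cfg["stable_log_decay"],
                estimator=cfg["estimator"],
                n_freq=cfg["n_freq"], n_lags=cfg["n_lags"],
                node_labels=ts.node_labels,
            )
            results["features"] = {
                "frequencies": model.frequencies,
                "csd": model.data.csd,
                "eigenvalues": model.mode_eigenvalues,
            }
            log(stage, t0)
        elif stage == "fit":
            fitres = model.fit(seed=cfg["seed"])
            results["fit"] = {
                "posterior_mean": fitres.posterior.mean,
                "posterior_cov": fitres.posterior.covariance,
                "free_energy": fitres.free_energy,
                "trace": fitres.posterior.trace,
                "jacobian": fitres.effective_connectivity()[0].jacobian,
            }
            log(stage, t0, free_energy_trace=list(fitres.posterior.trace))
        elif stage == "compare":
            m_values = cfg.get("m_values") or list(range(1, model.n_nodes + 1))
            table = cmp_mod.sweep_modes(model, m_values, cfg["stable_log_decay"],
                                        seed=cfg["seed"])
            table.to_csv(out_dir / "sweep_modes.tsv", sep="\t", index=False)
            results["compare"] = {"m": table["m"].tolist(), "F": table["F"].tolist()}
            log(stage, t0)
        elif stage == "project":
            source = fitres or model
            coords = scaling_mod.mds_coordinates(
                np.cov(ts.values, rowvar=False), cfg["mds_dimension"],
                node_labels=ts.node_labels,
            )
            pd.DataFrame(
                coords.coordinates,
                columns=[f"dim{k}" for k in range(coords.dimension)],
                index=list(coords.node_labels),
            ).to_csv(out_dir / "coordinates.tsv", sep="\t")
            results["project"] = {"coordinates": coords.coordinates}
            del source
            log(stage, t0)
    save_results(results, out_dir / "results.json")
    return results
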