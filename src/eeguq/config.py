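"""Run configuration: one YAML document driving the whole pipeline.

Conductivities are stated in mS/m exactly as in the tissue-prior table;
every section validates its sub-config before any computation starts,
and unknown keys are rejected by name so typos cannot silently fall
back to defaults.  An empty file yields the full default study setup
(80 electrodes, 50,000 Sobol samples per parameter, 1,000 sweep draws,
the standard prior intervals).
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .gpc import GPCConfig
from .model import (
    DEFAULT_LAYERS,
    DEFAULT_PRIORS,
    ConductivityPrior,
    Layer,
    SphereModel,
)

__all__ = ["RunConfig", "load_config"]

_DEFAULT_SOURCE_DEPTHS = [
    [2.5, 16], [5.0, 16], [7.5, 16], [10.0, 16], [12.5, 16],
    [15.0, 16], [20.0, 16], [25.0, 16], [30.0, 16], [35.0, 16],
    [40.0, 16], [45.0, 16],
]
_DEFAULT_SCAN_DEPTHS = [float(d) for d in np.arange(2.5, 46.0, 2.5)]


def _default_dict() -> dict:
    return {
        "model": {
            "radii": {t: r for t, r in DEFAULT_LAYERS},
            "series_truncation": 200,
            "truncation_tol": 1e-8,
        },
        "priors": {
            t: {"min": lo, "max": hi, "standard": st, "uncertain": unc}
            for t, (lo, hi, st, unc) in DEFAULT_PRIORS.items()
        },
        "montage": {"n_sensors": 80, "cap_half_angle": 110.0},
        "sources": {
            "depths": copy.deepcopy(_DEFAULT_SOURCE_DEPTHS),
            "orientation_scheme": "mixed",
            "dual_offset": 1.0,
        },
        "scan_grid": {"depths": list(_DEFAULT_SCAN_DEPTHS), "count": 48},
        "gpc": {
            "order": 8,
            "oversampling": 2.0,
            "n_fit_samples": None,
            "sampling": "low-discrepancy",
        },
        "sobol": {"n_samples": 50000, "pairs": [["skin", "skull"]], "n_boot": 200},
        "sweep": {"n_draws": 1000},
        "analysis": {
            "bin_width": 2.5,
            "depth_range": [0.0, 45.0],
            "center": "mean",
            "method": "pearson",
        },
        "seed": 0,
        "output_dir": "results",
    }


def _merge_strict(defaults: dict, given: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in given.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown config key: {here}")
        if isinstance(defaults[key], dict) and key not in ("radii", "priors"):
            if not isinstance(val, dict):
                raise ValueError(f"config key {here} must be a mapping")
            out[key] = _merge_strict(defaults[key], val, here)
        elif key == "priors":
            for t, p in val.items():
                base = out["priors"].get(t, {"min": None, "max": None, "standard": None, "uncertain": True})
                for k in p:
                    if k not in ("min", "max", "standard", "uncertain"):
                        raise ValueError(f"unknown config key: {here}.{t}.{k}")
                base = dict(base)
                base.update(p)
                out["priors"][t] = base
        else:
            out[key] = copy.deepcopy(val)
    return out


@dataclass
class RunConfig:
    """Validated pipeline configuration (see module docstring)."""

    raw: dict = field(default_factory=_default_dict)

    def __post_init__(self):
        # construct every sub-object once so all invariants fire up front
        self.model()
        self.priors()
        mon = self.raw["montage"]
        if mon["n_sensors"] < 4:
            raise ValueError("montage.n_sensors must be >= 4")
        if not (0 < mon["cap_half_angle"] <= 180):
            raise ValueError("montage.cap_half_angle must be in (0, 180]")
        for d, c in self.raw["sources"]["depths"]:
            if c < 1:
                raise ValueError(f"sources.depths: count {c} at depth {d} must be >= 1")
        if self.raw["sources"]["orientation_scheme"] not in ("radial", "tangential", "mixed"):
            raise ValueError("sources.orientation_scheme must be radial|tangential|mixed")
        self.gpc()
        if self.raw["sobol"]["n_samples"] < 2:
            raise ValueError("sobol.n_samples must be >= 2")
        if self.raw["sweep"]["n_draws"] < 1:
            raise ValueError("sweep.n_draws must be >= 1")
        if self.raw["analysis"]["bin_width"] <= 0:
            raise ValueError("analysis.bin_width must be positive")

    # -- constructors for the domain objects ------------------------------
    def model(self) -> SphereModel:
        m = self.raw["model"]
        layers = tuple(Layer(t, float(r)) for t, r in m["radii"].items())
        layers = tuple(sorted(layers, key=lambda ly: ly.outer_radius))
        return SphereModel(layers, int(m["series_truncation"]), float(m["truncation_tol"]))

    def priors(self) -> dict[str, ConductivityPrior]:
        out = {}
        for t, p in self.raw["priors"].items():
            try:
                out[t] = ConductivityPrior(t, float(p["min"]), float(p["max"]), float(p["standard"]), bool(p["uncertain"]))
            except (TypeError, ValueError) as exc:
                raise ValueError(f"priors.{t}: {exc}") from exc
        return out

    def gpc(self) -> GPCConfig:
        g = self.raw["gpc"]
        return GPCConfig(
            order=int(g["order"]),
            oversampling=float(g["oversampling"]),
            n_fit_samples=None if g["n_fit_samples"] is None else int(g["n_fit_samples"]),
            sampling=str(g["sampling"]),
            seed=int(self.raw["seed"]),
        )

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def output_dir(self) -> str:
        return str(self.raw["output_dir"])

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return copy.deepcopy(self.raw)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=float).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def with_overrides(self, **kv) -> "RunConfig":
        """Copy with dotted-path overrides, e.g. ``('sobol.n_samples', 4096)``."""
        raw = self.to_dict()
        for dotted, val in kv.items():
            parts = dotted.split("__")
            node = raw
            for p in parts[:-1]:
                node = node[p]
            node[parts[-1]] = val
        return RunConfig(_merge_strict(_default_dict(), raw))


def load_config(path=None) -> RunConfig:
    """Load and validate a YAML config; missing keys fall to defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    given = yaml.safe_load(text) or {}
    if not isinstance(given, dict):
        raise ValueError("config file must contain a YAML mapping")
    return RunConfig(_merge_strict(_default_dict(), given))
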