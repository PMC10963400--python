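"""Synthetic multilayer-sphere volume conductor.

This module provides the geometric side of the pipeline: a concentric
5-shell sphere head model (white matter, gray matter, CSF, skull, skin),
uniform conductivity priors per tissue, a deterministic scalp electrode
montage, and paired primary/dual source grids.  The dual grid is offset
from the primary grid so that inverse scans never run on the exact
discretization that generated the data (the classic inverse-crime guard).

Units: all radii and positions are millimetres, conductivities are mS/m
at the API surface (the forward solver converts internally).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Layer",
    "SphereModel",
    "ConductivityPrior",
    "ConductivitySet",
    "SensorMontage",
    "SourceSpace",
    "default_model",
    "default_priors",
    "standard_conductivities",
    "generate_montage",
    "generate_source_spaces",
    "source_depth",
    "read_positions",
    "write_positions",
    "write_sfp",
]

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))

#: Default shell radii in mm, inside -> out.  Chosen so that gray-matter
#: sources span depths of roughly 2-13 mm below the inner skull and deep
#: sources can reach 45 mm, matching the depth axis used throughout the
#: analyses.
DEFAULT_LAYERS = (
    ("wm", 67.0),
    ("gm", 78.0),
    ("csf", 80.0),
    ("skull", 86.0),
    ("skin", 92.0),
)

#: Uniform conductivity priors in mS/m: (min, max, standard, uncertain).
#: CSF is treated as known (negligible inter-individual variation).
DEFAULT_PRIORS = {
    "skin": (280.0, 870.0, 430.0, True),
    "skull": (1.6, 33.0, 10.0, True),
    "csf": (1769.6, 1810.4, 1790.0, False),
    "gm": (220.0, 670.0, 330.0, True),
    "wm": (90.0, 290.0, 140.0, True),
}


@dataclass(frozen=True)
class Layer:
    tissue: str
    outer_radius: float  # mm


@dataclass(frozen=True)
class SphereModel:
    """Concentric-shell head model.

    Parameters
    ----------
    layers
        Ordered inside -> out; each layer is the region between the
        previous layer's outer radius and its own.
    series_truncation
        Maximum Legendre degree of the forward series.
    truncation_tol
        Relative tail tolerance at which the series is cut off early.
    """

    layers: tuple[Layer, ...] = tuple(Layer(t, r) for t, r in DEFAULT_LAYERS)
    series_truncation: int = 200
    truncation_tol: float = 1e-8

    def __post_init__(self):
        radii = [ly.outer_radius for ly in self.layers]
        if len(self.layers) < 2:
            raise ValueError("SphereModel needs at least two layers")
        if radii[0] <= 0 or any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError(f"layer radii must be strictly increasing and positive, got {radii}")
        names = [ly.tissue for ly in self.layers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate tissue names in {names}")
        if self.series_truncation < 10:
            raise ValueError("series_truncation must be >= 10")

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(ly.tissue for ly in self.layers)

    @property
    def radii(self) -> np.ndarray:
        """Outer radii in mm, inside -> out."""
        return np.array([ly.outer_radius for ly in self.layers])

    @property
    def skin_radius(self) -> float:
        return self.layers[-1].outer_radius

    @property
    def skull_index(self) -> int:
        try:
            return self.tissues.index("skull")
        except ValueError:
            raise ValueError("model has no 'skull' layer") from None

    @property
    def inner_skull_radius(self) -> float:
        """Radius of the inner skull surface (depth reference), mm."""
        return self.layers[self.skull_index - 1].outer_radius

    @property
    def brain_radius(self) -> float:
        """Outer radius of the outermost brain compartment (GM), mm."""
        if "gm" in self.tissues:
            return self.layers[self.tissues.index("gm")].outer_radius
        return self.layers[0].outer_radius

    def layer_of(self, radius_mm: float) -> int:
        """Index of the layer containing the given radius."""
        for i, ly in enumerate(self.layers):
            if radius_mm < ly.outer_radius:
                return i
        raise ValueError(f"radius {radius_mm} mm lies outside the skin radius {self.skin_radius} mm")


@dataclass(frozen=True)
class ConductivityPrior:
    """Uniform prior for one tissue conductivity, in mS/m."""

    tissue: str
    sigma_min: float
    sigma_max: float
    sigma_standard: float
    uncertain: bool = True

    def __post_init__(self):
        if not (0.0 < self.sigma_min <= self.sigma_standard <= self.sigma_max):
            raise ValueError(
                f"{self.tissue}: need 0 < sigma_min <= sigma_standard <= sigma_max, "
                f"got ({self.sigma_min}, {self.sigma_standard}, {self.sigma_max})"
            )

    @property
    def mean(self) -> float:
        return 0.5 * (self.sigma_min + self.sigma_max)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.sigma_max - self.sigma_min)


def default_model() -> SphereModel:
    return SphereModel()


def default_priors() -> dict[str, ConductivityPrior]:
    return {
        t: ConductivityPrior(t, lo, hi, st, unc)
        for t, (lo, hi, st, unc) in DEFAULT_PRIORS.items()
    }


def uncertain_tissues(priors: dict[str, ConductivityPrior]) -> tuple[str, ...]:
    return tuple(t for t, p in priors.items() if p.uncertain)


@dataclass(frozen=True)
class ConductivitySet:
    """One concrete conductivity assignment, tissue -> mS/m."""

    values: tuple[tuple[str, float], ...]

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ConductivitySet":
        return cls(tuple(sorted(d.items())))

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)

    def __getitem__(self, tissue: str) -> float:
        return self.as_dict()[tissue]

    def validate(self, model: SphereModel, priors: dict[str, ConductivityPrior] | None = None) -> None:
        d = self.as_dict()
        for t in model.tissues:
            if t not in d:
                raise ValueError(f"conductivity set is missing tissue {t!r}")
            if d[t] <= 0:
                raise ValueError(f"non-positive conductivity for {t!r}: {d[t]}")
        if priors is not None:
            for t, p in priors.items():
                if t not in d:
                    continue
                if p.uncertain and not (p.sigma_min - 1e-12 <= d[t] <= p.sigma_max + 1e-12):
                    raise ValueError(
                        f"{t} conductivity {d[t]} outside prior [{p.sigma_min}, {p.sigma_max}] mS/m"
                    )


def standard_conductivities(priors: dict[str, ConductivityPrior] | None = None) -> ConductivitySet:
    priors = priors if priors is not None else default_priors()
    return ConductivitySet.from_dict({t: p.sigma_standard for t, p in priors.items()})


@dataclass(frozen=True)
class SensorMontage:
    labels: tuple[str, ...]
    positions: np.ndarray  # (M, 3) mm, on the scalp sphere

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (M, 3)")
        if len(self.labels) != pos.shape[0]:
            raise ValueError("labels and positions length mismatch")
        # pairwise distinct
        tree = cKDTree(pos)
        d, _ = tree.query(pos, k=2)
        if pos.shape[0] > 1 and np.min(d[:, 1]) <= 1e-9:
            raise ValueError("montage contains coincident electrode positions")

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]

    def validate_on(self, model: SphereModel) -> None:
        r = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(r, model.skin_radius, rtol=1e-9, atol=0.0):
            raise ValueError("electrode positions are not on the skin sphere")


@dataclass(frozen=True)
class SourceSpace:
    positions: np.ndarray  # (N, 3) mm
    orientations: np.ndarray  # (N, 3) unit vectors
    depths: np.ndarray  # (N,) mm below the inner skull surface
    role: str = "primary"  # 'primary' | 'dual'
    nn_to_companion: np.ndarray | None = None  # per-point distance to the paired grid

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        ori = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        dep = np.atleast_1d(np.asarray(self.depths, dtype=float))
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "orientations", ori)
        object.__setattr__(self, "depths", dep)
        if pos.shape != ori.shape or pos.shape[0] != dep.shape[0]:
            raise ValueError("positions, orientations and depths must align")
        norms = np.linalg.norm(ori, axis=1)
        if not np.allclose(norms, 1.0, rtol=0.0, atol=1e-9):
            raise ValueError("orientations must be unit vectors")
        if self.role not in ("primary", "dual"):
            raise ValueError(f"role must be 'primary' or 'dual', got {self.role!r}")
        if np.any(dep < -1e-9):
            raise ValueError("negative source depth")

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]

    @property
    def mean_nn_distance(self) -> float:
        if self.nn_to_companion is None:
            raise ValueError("no companion grid distances recorded")
        return float(np.mean(self.nn_to_companion))

    @property
    def max_nn_distance(self) -> float:
        if self.nn_to_companion is None:
            raise ValueError("no companion grid distances recorded")
        return float(np.max(self.nn_to_companion))

    def subset(self, idx) -> "SourceSpace":
        idx = np.atleast_1d(np.asarray(idx, dtype=int))
        return replace(
            self,
            positions=self.positions[idx],
            orientations=self.orientations[idx],
            depths=self.depths[idx],
            nn_to_companion=None if self.nn_to_companion is None else self.nn_to_companion[idx],
        )


def source_depth(model: SphereModel, position) -> float:
    """Depth of a source below the inner skull surface, in mm."""
    r = float(np.linalg.norm(np.asarray(position, dtype=float)))
    r_in = model.inner_skull_radius
    if r > r_in * (1 + 1e-12):
        raise ValueError(f"position at radius {r:.6g} mm lies outside the inner skull ({r_in} mm)")
    return r_in - r


def _fibonacci_cap(n: int, half_angle_deg: float) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors on a polar cap."""
    i = np.arange(n)
    z_min = math.cos(math.radians(half_angle_deg))
    z = 1.0 - (i + 0.5) / n * (1.0 - z_min)
    phi = _GOLDEN_ANGLE * i
    s = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def generate_montage(model: SphereModel, n_sensors: int = 80, cap_half_angle: float = 110.0) -> SensorMontage:
    """Deterministic Fibonacci-lattice electrode cap on the scalp sphere.

    The cap emulates an extended 10-10-style coverage; with the default
    half-angle the lowest electrodes sit well below the equator, as real
    EEG caps do.
    """
    if n_sensors < 4:
        raise ValueError("need at least 4 electrodes")
    if not (0.0 < cap_half_angle <= 180.0):
        raise ValueError("cap_half_angle must be in (0, 180] degrees")
    pos = _fibonacci_cap(n_sensors, cap_half_angle) * model.skin_radius
    labels = tuple(f"E{i + 1:03d}" for i in range(n_sensors))
    return SensorMontage(labels, pos)


def _tangent_frame(unit_pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local east/north unit vectors at each point of a unit sphere."""
    z = np.array([0.0, 0.0, 1.0])
    east = np.cross(z, unit_pos)
    nrm = np.linalg.norm(east, axis=1, keepdims=True)
    # points never sit exactly at the poles for the Fibonacci lattice
    east = east / nrm
    north = np.cross(unit_pos, east)
    return east, north


def generate_source_spaces(
    model: SphereModel,
    depth_spec: list[tuple[float, int]],
    orientation_scheme: str = "mixed",
    dual_offset: float = 1.0,
    seed: int = 0,
) -> tuple[SourceSpace, SourceSpace]:
    """Build the paired primary/dual source grids.

    Per requested depth, points are placed quasi-uniformly (Fibonacci
    lattice) on the sphere of radius ``inner_skull - depth``.  The dual
    grid is the same lattice pushed ``dual_offset`` mm deeper and rotated
    about z by a small angle chosen so the azimuthal displacement is at
    most ``dual_offset`` mm; every dual point therefore sits 1-2 offsets
    away from its primary partner, emulating the sub-millimetre
    vertex-to-dual-vertex distances of a triangulated cortex and its dual
    mesh, while no dual point coincides with a primary point.
    Per-primary-point nearest-dual distances are recorded on both
    returned spaces; their mean is the unavoidable discretization floor
    of the inverse scan and their max the corresponding worst case.

    ``orientation_scheme``: 'radial', 'tangential', or 'mixed'
    (alternating).  Tangential directions are drawn deterministically
    from ``seed`` in the local tangent plane.
    """
    if orientation_scheme not in ("radial", "tangential", "mixed"):
        raise ValueError(f"unknown orientation scheme {orientation_scheme!r}")
    r_in = model.inner_skull_radius
    rng = np.random.default_rng(seed)
    prim_pos, prim_ori, prim_dep = [], [], []
    dual_pos, dual_ori, dual_dep = [], [], []
    for depth, count in depth_spec:
        if count < 1:
            raise ValueError("source count per depth must be >= 1")
        if depth >= r_in:
            raise ValueError(f"depth {depth} mm is not smaller than the inner skull radius {r_in} mm")
        if depth + dual_offset >= r_in:
            raise ValueError(f"dual grid at depth {depth + dual_offset} mm would reach the origin")
        unit = _fibonacci_cap(count, 180.0)
        radius = r_in - depth
        prim_pos.append(unit * radius)
        prim_dep.append(np.full(count, depth))
        east, north = _tangent_frame(unit)
        angles = rng.uniform(0.0, 2.0 * math.pi, size=count)
        tang = np.cos(angles)[:, None] * east + np.sin(angles)[:, None] * north
        if orientation_scheme == "radial":
            ori = unit.copy()
        elif orientation_scheme == "tangential":
            ori = tang
        else:
            ori = np.where((np.arange(count) % 2 == 0)[:, None], unit, tang)
        prim_ori.append(ori)
        # dual: lattice pushed one offset deeper, rotated so the azimuthal
        # shift never exceeds the radial one
        delta = dual_offset / radius
        cd, sd = math.cos(delta), math.sin(delta)
        rot_z = np.array([[cd, -sd, 0.0], [sd, cd, 0.0], [0.0, 0.0, 1.0]])
        dunit = unit @ rot_z.T
        dual_pos.append(dunit * (radius - dual_offset))
        dual_dep.append(np.full(count, depth + dual_offset))
        dual_ori.append(dunit.copy())  # dual orientations are not used by the scan
    P = np.vstack(prim_pos)
    D = np.vstack(dual_pos)
    tree = cKDTree(D)
    nn, _ = tree.query(P, k=1)
    if np.min(cKDTree(P).query(D, k=1)[0]) <= 1e-9:
        raise ValueError("primary and dual grids share a coincident point")
    primary = SourceSpace(P, np.vstack(prim_ori), np.concatenate(prim_dep), "primary", nn)
    dual = SourceSpace(D, np.vstack(dual_ori), np.concatenate(dual_dep), "dual", nn)
    return primary, dual


# ---------------------------------------------------------------------------
# Position-table I/O: delimited text with columns label, x, y, z (mm)

def write_positions(path, labels, positions, sep: str = "\t") -> None:
    df = pd.DataFrame(np.asarray(positions, dtype=float), columns=["x", "y", "z"])
    df.insert(0, "label", list(labels))
    df.to_csv(path, sep=sep, index=False)


def read_positions(path, sep: str = "\t") -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep=sep)
    expected = ["label", "x", "y", "z"]
    if list(df.columns) != expected:
        raise ValueError(f"expected columns {expected}, got {list(df.columns)}")
    return df["label"].astype(str).tolist(), df[["x", "y", "z"]].to_numpy(dtype=float)


def write_sfp(path, labels, positions) -> None:
    """EEG .sfp-style writer: 'label x y z' per line, no header."""
    pos = np.asarray(positions, dtype=float)
    with open(path, "w") as fh:
        for lab, (x, y, z) in zip(labels, pos):
            fh.write(f"{lab}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")
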