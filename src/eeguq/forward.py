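"""Analytic EEG forward solution for a current dipole in concentric shells.

The quasi-static potential of a dipole inside a layered sphere separates
in spherical harmonics: within each shell the degree-n radial part is
``A r^n + B r^-(n+1)``, glued together by continuity of the potential
and of the radial current density ``sigma dV/dr`` at every interface,
with the dipole entering through the known infinite-medium (particular)
solution in its own shell and a zero-current condition at the scalp.

The per-degree coefficient systems are assembled with radius-scaled
basis functions ``(r/R_l)^n`` and ``(R_l/r)^(n+1)`` so the matrices stay
well conditioned up to high Legendre degree, and are solved in one
batched ``numpy.linalg.solve`` call per chunk of degrees.  The series is
truncated early once the relative tail drops below the model tolerance.

All returned potentials are average-referenced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import ConductivitySet, SensorMontage, SourceSpace, SphereModel

__all__ = [
    "PotentialVector",
    "Leadfield",
    "SeriesConvergenceWarning",
    "dipole_forward",
    "assemble_leadfield",
    "homogeneous_sphere_potential",
    "average_reference",
]

_CHUNK = 20  # degrees solved per batched linear-algebra call


class SeriesConvergenceWarning(UserWarning):
    """Raised when the Legendre series tail exceeds the model tolerance."""


def average_reference(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    return values - values.mean(axis=-1, keepdims=True)


@dataclass(frozen=True)
class PotentialVector:
    """Average-referenced electrode potentials (one value per sensor)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", v)
        norm = np.linalg.norm(v)
        if norm > 0 and abs(v.sum()) > 1e-9 * norm:
            raise ValueError("potential vector is not average-referenced")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class Leadfield:
    """Per source an (M, 3) average-referenced block, one column per
    Cartesian unit moment."""

    values: np.ndarray  # (n_sources, M, 3)
    sigma: ConductivitySet
    role: str = "primary"
    positions: np.ndarray | None = None  # (n_sources, 3) mm, if known

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 2:
            v = v[None]
        if v.ndim != 3 or v.shape[2] != 3:
            raise ValueError("leadfield must have shape (n_sources, M, 3)")
        object.__setattr__(self, "values", v)

    @property
    def n_sources(self) -> int:
        return self.values.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.values.shape[1]

    def block(self, i: int) -> np.ndarray:
        return self.values[i]

    def potential(self, i: int, moment: np.ndarray) -> PotentialVector:
        return PotentialVector(self.values[i] @ np.asarray(moment, dtype=float))


# ---------------------------------------------------------------------------
# geometry helpers

def _source_frame(source_pos: np.ndarray) -> tuple[float, np.ndarray]:
    """Rotation taking the source onto the +z axis.

    Returns (b, R) with b the source radius and R the 3x3 matrix whose
    rows are the rotated-frame unit vectors (x', y', z'=source direction).
    """
    p = np.asarray(source_pos, dtype=float)
    b = float(np.linalg.norm(p))
    zhat = p / b
    # any vector not parallel to zhat seeds the tangent pair
    seed = np.array([1.0, 0.0, 0.0]) if abs(zhat[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    xhat = seed - np.dot(seed, zhat) * zhat
    xhat /= np.linalg.norm(xhat)
    yhat = np.cross(zhat, xhat)
    return b, np.vstack([xhat, yhat, zhat])


def _legendre_tables(nmax: int, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """P_n(x) and T_n = sin(theta) P_n'(x) for n = 0..nmax, x = cos(theta).

    Shapes (nmax+1, len(x)).  T_n is the angular factor of the
    tangential-dipole terms; it vanishes at the poles.
    """
    x = np.asarray(x, dtype=float)
    P = np.empty((nmax + 1, x.size))
    P[0] = 1.0
    if nmax >= 1:
        P[1] = x
    for n in range(1, nmax):
        P[n + 1] = ((2 * n + 1) * x * P[n] - n * P[n - 1]) / (n + 1)
    sin_t = np.sqrt(np.clip(1.0 - x**2, 0.0, None))
    T = np.zeros_like(P)
    safe = sin_t > 1e-12
    for n in range(1, nmax + 1):
        # (1 - x^2) P_n' = n (P_{n-1} - x P_n)
        T[n, safe] = n * (P[n - 1, safe] - x[safe] * P[n, safe]) / sin_t[safe]
    return P, T


# ---------------------------------------------------------------------------
# per-degree coefficient systems

def _surface_coefficients(
    radii_m: np.ndarray,
    sigmas: np.ndarray,
    b_m: float,
    src_layer: int,
    degrees: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Outer-surface series coefficients W_rad(n), W_tan(n).

    For a unit radial (tangential) dipole moment at radius ``b_m`` in
    layer ``src_layer``, the scalp potential contribution of degree n is
    ``W_rad(n) P_n(cos t)`` resp. ``W_tan(n) T_n(t) cos(phi)``.
    """
    L = len(radii_m)
    nun = 2 * L - 1  # unknowns: A_1, then (A_l, B_l) for l = 2..L
    nd = degrees.size
    n = degrees.astype(float)[:, None, None]  # broadcast helper
    M = np.zeros((nd, nun, nun))
    rhs = np.zeros((nd, nun, 2))  # columns: radial, tangential

    def a_idx(l):  # A-coefficient column of layer l (0-based)
        return 0 if l == 0 else 2 * l - 1

    def b_idx(l):
        if l == 0:
            raise IndexError
        return 2 * l

    ns = degrees.astype(float)
    K = 1.0 / (4.0 * np.pi * sigmas[src_layer])  # unit moment
    inv_b2 = 1.0 / b_m**2

    def p_inner(r):  # particular solution below the source, and r * dV/dr
        rad = -K * (ns + 1.0) * (r / b_m) ** ns * inv_b2
        tan = K * (r / b_m) ** ns * inv_b2
        return rad, tan, ns * rad, ns * tan

    def p_outer(r):  # particular solution above the source
        rad = K * ns * (b_m / r) ** (ns + 1.0) * inv_b2
        tan = K * (b_m / r) ** (ns + 1.0) * inv_b2
        return rad, tan, -(ns + 1.0) * rad, -(ns + 1.0) * tan

    row = 0
    for l in range(L - 1):  # interface between layer l and l+1 at radii_m[l]
        r_if = radii_m[l]
        f1_up = (r_if / radii_m[l + 1]) ** ns  # layer l+1 basis at the interface
        f2_up = (radii_m[l + 1] / r_if) ** (ns + 1.0)
        # potential continuity
        M[:, row, a_idx(l)] = 1.0
        if l > 0:
            M[:, row, b_idx(l)] = 1.0
        M[:, row, a_idx(l + 1)] = -f1_up
        M[:, row, b_idx(l + 1)] = -f2_up
        # current continuity (times r_if)
        M[:, row + 1, a_idx(l)] = sigmas[l] * ns
        if l > 0:
            M[:, row + 1, b_idx(l)] = -sigmas[l] * (ns + 1.0)
        M[:, row + 1, a_idx(l + 1)] = -sigmas[l + 1] * ns * f1_up
        M[:, row + 1, b_idx(l + 1)] = sigmas[l + 1] * (ns + 1.0) * f2_up
        if l == src_layer:  # source below this interface
            vr, vt, jr, jt = p_outer(r_if)
            rhs[:, row, 0] -= vr
            rhs[:, row, 1] -= vt
            rhs[:, row + 1, 0] -= sigmas[l] * jr
            rhs[:, row + 1, 1] -= sigmas[l] * jt
        if l + 1 == src_layer:  # source above this interface
            vr, vt, jr, jt = p_inner(r_if)
            rhs[:, row, 0] += vr
            rhs[:, row, 1] += vt
            rhs[:, row + 1, 0] += sigmas[l + 1] * jr
            rhs[:, row + 1, 1] += sigmas[l + 1] * jt
        row += 2
    # insulating scalp: sigma_L dV/dr = 0 at the outer radius
    M[:, row, a_idx(L - 1)] = ns
    M[:, row, b_idx(L - 1)] = -(ns + 1.0)
    if src_layer == L - 1:
        _, _, jr, jt = p_outer(radii_m[-1])
        rhs[:, row, 0] -= jr
        rhs[:, row, 1] -= jt

    coef = np.linalg.solve(M, rhs)
    # scalp potential: basis functions of the outer layer are 1 at its radius
    w = coef[:, a_idx(L - 1), :] + coef[:, b_idx(L - 1), :]
    return w[:, 0], w[:, 1]


def _basis_potentials(
    model: SphereModel,
    sigma: ConductivitySet,
    source_pos: np.ndarray,
    montage: SensorMontage,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Scalp potentials (not yet referenced) for unit moments along the
    rotated-frame axes: returns (u_tx, u_ty, u_rad, frame)."""
    sigma.validate(model)
    p = np.asarray(source_pos, dtype=float)
    b_mm = float(np.linalg.norm(p))
    if b_mm < 1e-9:
        raise ValueError("source at the sphere center is not supported")
    if b_mm >= model.brain_radius:
        raise ValueError(
            f"source at radius {b_mm:.6g} mm lies outside the brain compartments "
            f"(outer brain radius {model.brain_radius} mm)"
        )
    for r_l in model.radii:
        if abs(b_mm - r_l) <= 1e-9 * r_l:
            raise ValueError(f"source sits on the layer interface at {r_l} mm")
    sig = np.array([sigma[t] for t in model.tissues]) * 1e-3  # mS/m -> S/m
    if np.any(sig <= 0):
        raise ValueError("non-positive conductivity")
    radii_m = model.radii * 1e-3
    b_m = b_mm * 1e-3
    src_layer = model.layer_of(b_mm)

    b_chk, frame = _source_frame(p)
    e = montage.positions @ frame.T  # electrodes in the rotated frame, mm
    r_e = np.linalg.norm(e, axis=1)
    cos_t = np.clip(e[:, 2] / r_e, -1.0, 1.0)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_p = np.where(sin_t > 1e-12, e[:, 0] / (r_e * sin_t), 0.0)
        sin_p = np.where(sin_t > 1e-12, e[:, 1] / (r_e * sin_t), 0.0)

    nmax = model.series_truncation
    P, T = _legendre_tables(nmax, cos_t)
    u_rad = np.zeros(montage.n_sensors)
    u_tan = np.zeros(montage.n_sensors)
    scale = None
    converged = False
    tail = np.inf
    for start in range(1, nmax + 1, _CHUNK):
        degrees = np.arange(start, min(start + _CHUNK, nmax + 1))
        w_rad, w_tan = _surface_coefficients(radii_m, sig, b_m, src_layer, degrees)
        du_rad = w_rad @ P[degrees]
        du_tan = w_tan @ T[degrees]
        u_rad += du_rad
        u_tan += du_tan
        scale = max(np.max(np.abs(u_rad)), np.max(np.abs(u_tan)), 1e-300)
        tail = max(np.max(np.abs(du_rad)), np.max(np.abs(du_tan))) / scale
        if tail < model.truncation_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"Legendre series not converged at degree {nmax}: relative tail ~{tail:.2e}",
            SeriesConvergenceWarning,
            stacklevel=3,
        )
    return u_tan * cos_p, u_tan * sin_p, u_rad, frame


def dipole_forward(
    model: SphereModel,
    sigma: ConductivitySet,
    source_pos,
    moment,
    montage: SensorMontage,
) -> PotentialVector:
    """Electrode potentials of a current dipole, average-referenced.

    ``moment`` is a Cartesian dipole moment; the result is linear in it.
    Potentials are in volts per unit moment with positions in mm and
    conductivities in mS/m (the absolute scale cancels in all the error
    measures downstream; only consistency matters).
    """
    u_tx, u_ty, u_rad, frame = _basis_potentials(model, sigma, np.asarray(source_pos), montage)
    m = frame @ np.asarray(moment, dtype=float)
    u = m[0] * u_tx + m[1] * u_ty + m[2] * u_rad
    return PotentialVector(average_reference(u))


def assemble_leadfield(
    model: SphereModel,
    sigma: ConductivitySet,
    sources: SourceSpace,
    montage: SensorMontage,
) -> Leadfield:
    """(M, 3) forward block per source; column k is the unit-moment
    solution along Cartesian axis k."""
    blocks = np.empty((sources.n_sources, montage.n_sensors, 3))
    for i in range(sources.n_sources):
        try:
            u_tx, u_ty, u_rad, frame = _basis_potentials(model, sigma, sources.positions[i], montage)
        except ValueError as exc:
            raise ValueError(f"source {i}: {exc}") from exc
        # column k = potentials of unit moment e_k; e_k in the rotated
        # frame has components frame[:, k]
        block = (
            np.outer(u_tx, frame[0])
            + np.outer(u_ty, frame[1])
            + np.outer(u_rad, frame[2])
        )
        blocks[i] = average_reference(block.T).T
    return Leadfield(blocks, sigma, sources.role, sources.positions.copy())


# ---------------------------------------------------------------------------
# independent closed-form reference: homogeneous sphere

def homogeneous_sphere_potential(
    radius_mm: float,
    sigma_mSm: float,
    source_pos,
    moment,
    electrode_positions,
) -> np.ndarray:
    """Closed-form scalp potential of a dipole in a homogeneous sphere.

    Classical result for a current dipole inside a uniformly conducting
    sphere with insulating boundary; used as the analytic oracle for the
    layered series in the equal-conductivity limit.  Returns raw (not
    average-referenced) potentials with the implicit zero-mean-on-sphere
    reference of the multipole series.
    """
    p = np.asarray(source_pos, dtype=float)
    m = np.asarray(moment, dtype=float)
    E = np.asarray(electrode_positions, dtype=float)
    R = radius_mm * 1e-3
    b = np.linalg.norm(p) * 1e-3
    sig = sigma_mSm * 1e-3
    zhat = p / np.linalg.norm(p)
    seed = np.array([1.0, 0.0, 0.0]) if abs(zhat[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    xhat = seed - np.dot(seed, zhat) * zhat
    xhat /= np.linalg.norm(xhat)
    yhat = np.cross(zhat, xhat)
    e = E @ np.vstack([xhat, yhat, zhat]).T * 1e-3
    r_e = np.linalg.norm(e, axis=1)
    c = np.clip(e[:, 2] / r_e, -1.0, 1.0)
    s = np.sqrt(np.clip(1.0 - c**2, 0.0, None))
    f = b / R
    g = np.sqrt(1.0 - 2.0 * f * c + f**2)
    m_loc = np.array([np.dot(m, xhat), np.dot(m, yhat), np.dot(m, zhat)])
    pref = 1.0 / (4.0 * np.pi * sig * R**2)
    # sum_n (2n+1) f^(n-1) P_n(c)
    v_rad = pref * (2.0 * (c - f) / g**3 + (1.0 / g - 1.0) / f)
    # sum_n ((2n+1)/n) f^(n-1) sin(t) P_n'(c)
    with np.errstate(invalid="ignore", divide="ignore"):
        tan_series = 2.0 / g**3 + (f - c + c * g) / (f * (1.0 - c**2) * g)
    tan_series = np.where(s > 1e-9, tan_series, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_phi = np.where(s > 1e-9, e[:, 0] / (r_e * s), 0.0)
        sin_phi = np.where(s > 1e-9, e[:, 1] / (r_e * s), 0.0)
    v_tan = pref * s * tan_series
    return m_loc[2] * v_rad + (m_loc[0] * cos_phi + m_loc[1] * sin_phi) * v_tan
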