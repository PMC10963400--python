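"""Topography and magnitude error measures.

The relative difference measure (RDM) is the Euclidean distance between
the two unit-normalized potential vectors and lives in [0, 2]; it
captures a change in signal *topography* and is invariant to rescaling
either argument.  The magnitude error (MAG) is the plain norm ratio
``||u_test|| / ||u_ref||`` and captures the *amplitude* change.  Both
are computed on average-referenced vectors throughout the package.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rdm", "mag"]


def _as_vector(u, name: str) -> np.ndarray:
    values = getattr(u, "values", u)
    return np.asarray(values, dtype=float).ravel()


def rdm(u_test, u_ref) -> float:
    """Relative difference measure between two potential vectors."""
    t = _as_vector(u_test, "u_test")
    r = _as_vector(u_ref, "u_ref")
    if t.shape != r.shape:
        raise ValueError(f"length mismatch: {t.size} vs {r.size}")
    nt = np.linalg.norm(t)
    nr = np.linalg.norm(r)
    if nt == 0.0:
        raise ValueError("u_test has zero norm")
    if nr == 0.0:
        raise ValueError("u_ref has zero norm")
    return float(np.linalg.norm(t / nt - r / nr))


def mag(u_test, u_ref) -> float:
    """Magnitude error: norm ratio of test over reference potentials."""
    t = _as_vector(u_test, "u_test")
    r = _as_vector(u_ref, "u_ref")
    nr = np.linalg.norm(r)
    if nr == 0.0:
        raise ValueError("u_ref has zero norm")
    return float(np.linalg.norm(t) / nr)


def rdm_many(U_test: np.ndarray, u_ref) -> np.ndarray:
    """Row-wise RDM of a (K, M) batch against one reference vector."""
    U = np.atleast_2d(np.asarray(U_test, dtype=float))
    r = _as_vector(u_ref, "u_ref")
    nr = np.linalg.norm(r)
    if nr == 0.0:
        raise ValueError("u_ref has zero norm")
    nt = np.linalg.norm(U, axis=1)
    if np.any(nt == 0.0):
        raise ValueError("a test vector has zero norm")
    return np.linalg.norm(U / nt[:, None] - r / nr, axis=1)


def mag_many(U_test: np.ndarray, u_ref) -> np.ndarray:
    """Row-wise MAG of a (K, M) batch against one reference vector."""
    U = np.atleast_2d(np.asarray(U_test, dtype=float))
    r = _as_vector(u_ref, "u_ref")
    nr = np.linalg.norm(r)
    if nr == 0.0:
        raise ValueError("u_ref has zero norm")
    return np.linalg.norm(U, axis=1) / nr
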