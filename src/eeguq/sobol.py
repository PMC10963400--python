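"""Variance-based sensitivity: pick-freeze Sobol indices via the Janon estimator.

A Sobol index is the fraction of an output's variance attributable to a
subset of inputs.  The pick-freeze scheme draws two independent sample
matrices A and B from the priors; for a subset u, the "swapped" matrix
A_B^(u) equals A except that the columns in u are taken row-wise from
B.  The rows of B and of A_B^(u) agree exactly in the columns of u and
are independent elsewhere, so with outputs y = f(B) and y_u = f(A_B^(u))
the Janon estimator of the *closed* index of u is

    S_hat = [ mean(y*y_u) - mean((y+y_u)/2)^2 ]
            / [ mean((y^2+y_u^2)/2) - mean((y+y_u)/2)^2 ]

which has optimal asymptotic variance among pick-freeze estimators.
First-order indices are closed indices of singletons; the pure
second-order interaction of {i, j} is the closed pair index minus both
first-order terms; the total effect of i is one minus the closed index
of the complement of {i}.

Monte-Carlo uncertainty is quantified by paired bootstrap over rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forward import dipole_forward
from .metrics import mag_many, rdm_many
from .model import (
    ConductivityPrior,
    ConductivitySet,
    SensorMontage,
    SourceSpace,
    SphereModel,
    standard_conductivities,
)

__all__ = [
    "PickFreezeDesign",
    "SobolEstimate",
    "sample_design",
    "janon_closed_index",
    "first_order",
    "second_order",
    "total_effect",
    "bootstrap_se",
    "default_subsets",
    "sobol_of_rdm_mag",
    "direct_forward_evaluator",
]

_VAR_EPS = 1e-14  # relative threshold for a degenerate (constant) output


@dataclass(frozen=True)
class PickFreezeDesign:
    """Paired sample matrices and the input subsets to be swapped."""

    tissues: tuple[str, ...]
    A: np.ndarray  # (N, d) draws, mS/m
    B: np.ndarray
    subsets: tuple[tuple[str, ...], ...]
    seed: int = 0

    def __post_init__(self):
        if self.A.shape != self.B.shape:
            raise ValueError("A and B must have identical shapes")
        if self.A.shape[0] < 2:
            raise ValueError("need at least 2 samples per matrix")
        for u in self.subsets:
            if not u:
                raise ValueError("empty subset")
            for t in u:
                if t not in self.tissues:
                    raise ValueError(f"subset tissue {t!r} is not an uncertain design tissue")

    @property
    def n_samples(self) -> int:
        return self.A.shape[0]

    def columns(self, subset) -> list[int]:
        return [self.tissues.index(t) for t in subset]

    def swapped(self, subset) -> np.ndarray:
        """A with the columns in ``subset`` replaced row-wise from B."""
        cols = self.columns(subset)
        out = self.A.copy()
        out[:, cols] = self.B[:, cols]
        return out

    def complement(self, tissue: str) -> tuple[str, ...]:
        return tuple(t for t in self.tissues if t != tissue)


def sample_design(
    priors: dict[str, ConductivityPrior],
    n_samples: int,
    subsets,
    seed: int = 0,
) -> PickFreezeDesign:
    """Draw the two independent prior-sample matrices.

    Only uncertain tissues enter the design; fixed tissues are excluded
    and referencing one in a subset is an error.
    """
    tissues = tuple(t for t, p in priors.items() if p.uncertain)
    subsets = tuple(tuple(u) for u in subsets)
    if not subsets:
        raise ValueError("subsets must be nonempty")
    for u in subsets:
        for t in u:
            if t not in tissues:
                raise ValueError(f"subset tissue {t!r} is fixed or unknown")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    lo = np.array([priors[t].sigma_min for t in tissues])
    hi = np.array([priors[t].sigma_max for t in tissues])
    ss = np.random.SeedSequence(seed)
    rng_a, rng_b = (np.random.default_rng(s) for s in ss.spawn(2))
    A = lo + rng_a.uniform(size=(n_samples, len(tissues))) * (hi - lo)
    B = lo + rng_b.uniform(size=(n_samples, len(tissues))) * (hi - lo)
    return PickFreezeDesign(tissues, A, B, subsets, seed)


def janon_closed_index(y: np.ndarray, y_u: np.ndarray) -> float:
    """Janon pick-freeze estimate of the closed Sobol index of a subset.

    ``y`` and ``y_u`` are the model outputs on the two pick-freeze
    matrices that share exactly the subset's columns (f(B) and
    f(A_B^(u)) in the module convention).  Returns 0.0 for a degenerate
    (zero empirical variance) output.
    """
    y = np.asarray(y, dtype=float).ravel()
    y_u = np.asarray(y_u, dtype=float).ravel()
    if y.shape != y_u.shape:
        raise ValueError(f"length mismatch: {y.size} vs {y_u.size}")
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    m = 0.5 * np.mean(y + y_u)
    num = np.mean(y * y_u) - m**2
    den = 0.5 * np.mean(y**2 + y_u**2) - m**2
    scale = 0.5 * np.mean(y**2 + y_u**2)
    if den <= _VAR_EPS * max(scale, 1e-300):
        return 0.0
    return float(num / den)


def is_degenerate(yA: np.ndarray) -> bool:
    yA = np.asarray(yA, dtype=float)
    v = np.var(yA)
    return bool(v <= _VAR_EPS * max(np.mean(yA**2), 1e-300))


def bootstrap_se(yA, yAu, n_boot: int = 200, seed: int = 0) -> float:
    """Paired-bootstrap standard error of the Janon estimate."""
    yA = np.asarray(yA, dtype=float).ravel()
    yAu = np.asarray(yAu, dtype=float).ravel()
    n = yA.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    a, b = yA[idx], yAu[idx]
    m = 0.5 * np.mean(a + b, axis=1)
    num = np.mean(a * b, axis=1) - m**2
    den = 0.5 * np.mean(a**2 + b**2, axis=1) - m**2
    ok = den > _VAR_EPS * np.maximum(0.5 * np.mean(a**2 + b**2, axis=1), 1e-300)
    est = np.where(ok, num / np.where(ok, den, 1.0), 0.0)
    return float(np.std(est, ddof=1))


def _resolve_outputs(design: PickFreezeDesign, outputs):
    """Outputs may be a callable model f((N, d) matrix) -> (N,) or a dict
    with key 'B' and one key per subset tuple."""
    if callable(outputs):
        cache = {"B": np.asarray(outputs(design.B), dtype=float)}
        for u in design.subsets:
            cache[u] = np.asarray(outputs(design.swapped(u)), dtype=float)
        return cache
    return outputs


def first_order(design: PickFreezeDesign, outputs) -> dict[str, float]:
    """First-order index per tissue (closed index of each singleton)."""
    out = _resolve_outputs(design, outputs)
    res = {}
    for t in design.tissues:
        key = (t,)
        if key not in out:
            raise ValueError(f"missing swapped-matrix outputs for singleton {key}")
        res[t] = janon_closed_index(out["B"], out[key])
    return res


def second_order(design: PickFreezeDesign, outputs, pair) -> float:
    """Pure interaction index of a pair: closed pair index minus both
    first-order terms.  May be slightly negative by Monte-Carlo noise."""
    pair = tuple(pair)
    out = _resolve_outputs(design, outputs)
    if pair not in out:
        raise ValueError(f"missing swapped-matrix outputs for pair {pair}")
    s_closed = janon_closed_index(out["B"], out[pair])
    s_i = janon_closed_index(out["B"], out[(pair[0],)])
    s_j = janon_closed_index(out["B"], out[(pair[1],)])
    return s_closed - s_i - s_j


def total_effect(design: PickFreezeDesign, outputs, tissue: str) -> float:
    """Total-effect index: one minus the closed index of the complement."""
    comp = design.complement(tissue)
    out = _resolve_outputs(design, outputs)
    if comp not in out:
        raise ValueError(f"missing swapped-matrix outputs for complement {comp}")
    if is_degenerate(out["B"]):
        return 0.0
    return 1.0 - janon_closed_index(out["B"], out[comp])


def default_subsets(tissues, pairs=()) -> tuple[tuple[str, ...], ...]:
    """Singletons, requested pairs, and every singleton's complement."""
    singles = [(t,) for t in tissues]
    comps = [tuple(s for s in tissues if s != t) for t in tissues]
    return tuple(singles + [tuple(p) for p in pairs] + comps)


@dataclass
class SobolEstimate:
    """Tidy table of Sobol estimates.

    One row per (source, functional, index-type, tissue-or-pair) with
    raw and clamped-to-[0,1] values, bootstrap SE, sample count and
    seed.  Raw values may fall slightly outside [0, 1]; both are kept.
    """

    table: pd.DataFrame
    n_samples: int
    seed: int

    def value(self, source: int, functional: str, kind: str, name: str, raw: bool = True) -> float:
        t = self.table
        row = t[
            (t.source == source) & (t.functional == functional) & (t.kind == kind) & (t.name == name)
        ]
        if len(row) != 1:
            raise KeyError((source, functional, kind, name))
        return float(row.raw.iloc[0] if raw else row.clamped.iloc[0])

    def to_csv(self, path, sep: str = "\t") -> None:
        self.table.to_csv(path, sep=sep, index=False)


def direct_forward_evaluator(model: SphereModel, montage: SensorMontage, sources: SourceSpace):
    """Row-by-row analytic forward evaluation with the same call shape as
    ``GPCSurrogate.potentials_batch`` — the surrogate-free oracle path."""
    from .gpc import GPCSurrogate  # noqa: F401  (interface twin)

    def evaluate(sig_matrix: np.ndarray, source: int, moment, tissues, fixed) -> np.ndarray:
        out = np.empty((sig_matrix.shape[0], montage.n_sensors))
        pos = sources.positions[source]
        for k, row in enumerate(sig_matrix):
            full = dict(fixed)
            full.update({t: float(v) for t, v in zip(tissues, row)})
            out[k] = dipole_forward(model, ConductivitySet.from_dict(full), pos, moment, montage).values
        return out

    return evaluate


def sobol_of_rdm_mag(
    surrogate,
    model: SphereModel,
    montage: SensorMontage,
    sources: SourceSpace,
    priors: dict[str, ConductivityPrior],
    n_samples: int,
    seed: int = 0,
    pairs=(("skin", "skull"),),
    n_boot: int = 200,
    source_indices=None,
) -> SobolEstimate:
    """Sobol indices of RDM and MAG per source.

    For every design row the potentials of the source's oriented dipole
    are evaluated (through the gPC surrogate, or through the direct
    forward evaluator returned by :func:`direct_forward_evaluator`),
    RDM and MAG are computed against the standard-conductivity reference
    solution, and first-order, requested second-order, and total-effect
    indices of both functionals are estimated.
    """
    from .gpc import GPCSurrogate

    tissues = tuple(t for t, p in priors.items() if p.uncertain)
    fixed = {t: p.sigma_standard for t, p in priors.items() if not p.uncertain}
    design = sample_design(priors, n_samples, default_subsets(tissues, pairs), seed)
    sigma_st = standard_conductivities(priors)
    idx = range(sources.n_sources) if source_indices is None else source_indices

    matrices = {"B": design.B}
    for u in design.subsets:
        matrices[u] = design.swapped(u)

    rows = []
    boot_seed = np.random.SeedSequence(seed).spawn(1)[0].generate_state(1)[0] % (2**31)
    for i in idx:
        moment = sources.orientations[i]
        u_ref = dipole_forward(model, sigma_st, sources.positions[i], moment, montage).values
        outs_rdm, outs_mag = {}, {}
        for key, mat in matrices.items():
            if isinstance(surrogate, GPCSurrogate):
                order = [surrogate.tissues.index(t) for t in tissues]
                U = surrogate.potentials_batch(mat[:, order] if order != list(range(len(tissues))) else mat, i, moment)
            else:
                U = surrogate(mat, i, moment, tissues, fixed)
            outs_rdm[key] = rdm_many(U, u_ref)
            outs_mag[key] = mag_many(U, u_ref)
        for functional, outs in (("rdm", outs_rdm), ("mag", outs_mag)):
            degen = is_degenerate(outs["B"])
            for t in tissues:
                raw = 0.0 if degen else janon_closed_index(outs["B"], outs[(t,)])
                se = bootstrap_se(outs["B"], outs[(t,)], n_boot, boot_seed)
                rows.append((i, functional, "first", t, raw, se, degen))
            for p in pairs:
                p = tuple(p)
                raw = 0.0 if degen else second_order(design, outs, p)
                se = bootstrap_se(outs["B"], outs[p], n_boot, boot_seed)
                rows.append((i, functional, "second", "-".join(p), raw, se, degen))
            for t in tissues:
                raw = 0.0 if degen else total_effect(design, outs, t)
                se = bootstrap_se(outs["B"], outs[design.complement(t)], n_boot, boot_seed)
                rows.append((i, functional, "total", t, raw, se, degen))
    df = pd.DataFrame(rows, columns=["source", "functional", "kind", "name", "raw", "se", "degenerate"])
    df["clamped"] = df["raw"].clip(0.0, 1.0)
    df["n"] = n_samples
    df["seed"] = seed
    return SobolEstimate(df, n_samples, seed)
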