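"""Stage orchestration: model -> surrogate -> sobol / sweep -> analyze.

Every stage writes delimited (TSV) tables prefixed with provenance
comment lines (config hash, global seed, stage name, package version),
and later stages consume earlier artifacts by path, refusing to run
with a named hint when an upstream product is missing.  One global seed
is split into independent per-stage substreams, so stages are
individually reproducible and mutually independent.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import build_correlation_profile, depth_profile, summarize_sweeps
from .config import RunConfig
from .forward import Leadfield, assemble_leadfield
from .gpc import GPCSurrogate, fit_gpc, validate_gpc
from .model import SensorMontage, SourceSpace, generate_montage, generate_source_spaces, standard_conductivities
from .scan import conductivity_sweep
from .sobol import sobol_of_rdm_mag

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("model", "surrogate", "sobol", "sweep", "analyze")
log = logging.getLogger("eeguq")


def _stage_seeds(seed: int) -> dict[str, int]:
    states = np.random.SeedSequence(seed).generate_state(len(STAGES))
    return {s: int(v % (2**31)) for s, v in zip(STAGES, states)}


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig, stage: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# eeguq={__version__} stage={stage} config_hash={cfg.hash} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_table(path: Path, needed_by: str, produced_by: str) -> pd.DataFrame:
    if not Path(path).exists():
        raise ValueError(
            f"stage '{needed_by}' needs {Path(path).name}, produced by stage '{produced_by}' — run it first"
        )
    return pd.read_csv(path, sep="\t", comment="#")


def _space_frame(space: SourceSpace) -> pd.DataFrame:
    df = pd.DataFrame(space.positions, columns=["x", "y", "z"])
    df.insert(0, "label", [f"S{i:04d}" for i in range(space.n_sources)])
    df[["ox", "oy", "oz"]] = space.orientations
    df["depth"] = space.depths
    if space.nn_to_companion is not None:
        df["nn_dist"] = space.nn_to_companion
    return df


def _space_from_frame(df: pd.DataFrame, role: str) -> SourceSpace:
    return SourceSpace(
        df[["x", "y", "z"]].to_numpy(),
        df[["ox", "oy", "oz"]].to_numpy(),
        df["depth"].to_numpy(),
        role,
        df["nn_dist"].to_numpy() if "nn_dist" in df else None,
    )


def _montage(cfg: RunConfig) -> SensorMontage:
    m = cfg.raw["montage"]
    return generate_montage(cfg.model(), int(m["n_sensors"]), float(m["cap_half_angle"]))


def run_pipeline(cfg: RunConfig, stages=STAGES, out_dir=None, direct: bool = False) -> dict[str, Path]:
    """Run the requested stages; returns the artifact paths written.

    ``direct=True`` bypasses the gPC surrogate in the sweep stage and
    simulates every measurement with the analytic forward solver.
    """
    stages = tuple(stages)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; choose from {STAGES}")
    out = Path(out_dir if out_dir is not None else cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    model = cfg.model()
    priors = cfg.priors()
    sigma_st = standard_conductivities(priors)
    montage = _montage(cfg)
    artifacts: dict[str, Path] = {}
    cfg.save(out / "config_used.yaml")

    if "model" in stages:
        t0 = time.perf_counter()
        primary, dual = generate_source_spaces(
            model,
            [(float(d), int(c)) for d, c in cfg.raw["sources"]["depths"]],
            cfg.raw["sources"]["orientation_scheme"],
            float(cfg.raw["sources"]["dual_offset"]),
            seeds["model"],
        )
        sg = cfg.raw["scan_grid"]
        _, scan_grid = generate_source_spaces(
            model,
            [(float(d), int(sg["count"])) for d in sg["depths"]],
            "radial",
            float(cfg.raw["sources"]["dual_offset"]),
            seeds["model"] + 1,
        )
        el = pd.DataFrame(montage.positions, columns=["x", "y", "z"])
        el.insert(0, "label", montage.labels)
        for name, df in (
            ("electrodes", el),
            ("sources_primary", _space_frame(primary)),
            ("sources_dual", _space_frame(dual)),
            ("scan_grid", _space_frame(scan_grid)),
        ):
            p = out / f"{name}.tsv"
            _write_table(df, p, cfg, "model")
            artifacts[name] = p
        log.info(
            "model stage: %d electrodes, %d primary / %d dual sources, %d scan points, "
            "mean primary->dual nn distance %.2f mm (%.2fs)",
            montage.n_sensors, primary.n_sources, dual.n_sources, scan_grid.n_sources,
            primary.mean_nn_distance, time.perf_counter() - t0,
        )

    if "surrogate" in stages:
        t0 = time.perf_counter()
        prim = _space_from_frame(_read_table(out / "sources_primary.tsv", "surrogate", "model"), "primary")
        fwd = lambda s: assemble_leadfield(model, s, prim, montage)  # noqa: E731
        gcfg = cfg.gpc()
        sur = fit_gpc(fwd, priors, gcfg)
        sur.save(out / "surrogate.npz")
        artifacts["surrogate"] = out / "surrogate.npz"
        rep = validate_gpc(sur, fwd, n_test=10, seed=seeds["surrogate"])
        _write_table(rep, out / "surrogate_validation.tsv", cfg, "surrogate")
        artifacts["surrogate_validation"] = out / "surrogate_validation.tsv"
        log.info(
            "surrogate stage: order %d, %d basis terms, max held-out RDM %.2e (%.1fs)",
            gcfg.order, len(sur.multi_indices), rep.rdm_max.max(), time.perf_counter() - t0,
        )

    if "sobol" in stages:
        t0 = time.perf_counter()
        prim = _space_from_frame(_read_table(out / "sources_primary.tsv", "sobol", "model"), "primary")
        if not (out / "surrogate.npz").exists():
            raise ValueError("stage 'sobol' needs surrogate.npz, produced by stage 'surrogate' — run it first")
        sur = GPCSurrogate.load(out / "surrogate.npz")
        sb = cfg.raw["sobol"]
        est = sobol_of_rdm_mag(
            sur, model, montage, prim, priors,
            int(sb["n_samples"]), seeds["sobol"],
            pairs=tuple(tuple(p) for p in sb["pairs"]),
            n_boot=int(sb["n_boot"]),
        )
        _write_table(est.table, out / "sobol_indices.tsv", cfg, "sobol")
        artifacts["sobol_indices"] = out / "sobol_indices.tsv"
        # depth profile of the first-order RDM skull index and friends
        prof_rows = []
        t = est.table
        depths = prim.depths
        for (functional, kind, name), grp in t.groupby(["functional", "kind", "name"]):
            vals = grp.sort_values("source").clamped.to_numpy()
            prof = depth_profile(
                vals, depths[grp.sort_values("source").source.to_numpy()],
                float(cfg.raw["analysis"]["bin_width"]),
                tuple(cfg.raw["analysis"]["depth_range"]),
            )
            prof.insert(0, "functional", functional)
            prof.insert(1, "kind", kind)
            prof.insert(2, "name", name)
            prof_rows.append(prof)
        _write_table(pd.concat(prof_rows, ignore_index=True), out / "sobol_depth_profiles.tsv", cfg, "sobol")
        artifacts["sobol_depth_profiles"] = out / "sobol_depth_profiles.tsv"
        log.info("sobol stage: %d sources x %d samples (%.1fs)", prim.n_sources, sb["n_samples"], time.perf_counter() - t0)

    if "sweep" in stages:
        t0 = time.perf_counter()
        prim = _space_from_frame(_read_table(out / "sources_primary.tsv", "sweep", "model"), "primary")
        grid = _space_from_frame(_read_table(out / "scan_grid.tsv", "sweep", "model"), "dual")
        dual_lf = assemble_leadfield(model, sigma_st, grid, montage)
        if direct:
            evaluator = None
        else:
            if not (out / "surrogate.npz").exists():
                raise ValueError("stage 'sweep' needs surrogate.npz, produced by stage 'surrogate' — run it first")
            evaluator = GPCSurrogate.load(out / "surrogate.npz")
        k = int(cfg.raw["sweep"]["n_draws"])
        sweeps = []
        frames = []
        for i in range(prim.n_sources):
            sw = conductivity_sweep(prim, i, priors, k, seeds["sweep"] + i, evaluator, dual_lf, model, montage)
            sweeps.append(sw)
            df = sw.draws.copy()
            df.insert(0, "source", i)
            frames.append(df)
        _write_table(pd.concat(frames, ignore_index=True), out / "sweep_draws.tsv", cfg, "sweep")
        _write_table(summarize_sweeps(sweeps), out / "sweep_summary.tsv", cfg, "sweep")
        artifacts["sweep_draws"] = out / "sweep_draws.tsv"
        artifacts["sweep_summary"] = out / "sweep_summary.tsv"
        log.info("sweep stage: %d sources x %d draws (%.1fs)", prim.n_sources, k, time.perf_counter() - t0)

    if "analyze" in stages:
        t0 = time.perf_counter()
        prim = _space_from_frame(_read_table(out / "sources_primary.tsv", "analyze", "model"), "primary")
        draws = _read_table(out / "sweep_draws.tsv", "analyze", "sweep")
        from .scan import SweepResult  # local import to rebuild sweep objects

        sweeps = []
        for i, grp in draws.groupby("source"):
            grp = grp.drop(columns=["source"]).reset_index(drop=True)
            xyz = grp[["reco_x", "reco_y", "reco_z"]].to_numpy()
            sweeps.append(
                SweepResult(
                    int(i), prim.positions[int(i)], prim.orientations[int(i)],
                    float(prim.depths[int(i)]), grp, xyz.mean(axis=0),
                )
            )
        an = cfg.raw["analysis"]
        profile = build_correlation_profile(
            sweeps, priors, an["center"], an["method"], float(an["bin_width"]), tuple(an["depth_range"])
        )
        _write_table(profile.per_source, out / "correlations.tsv", cfg, "analyze")
        prof_frames = []
        for key, df in profile.profiles.items():
            df = df.copy()
            df.insert(0, "analysis", key)
            prof_frames.append(df)
        _write_table(pd.concat(prof_frames, ignore_index=True), out / "correlation_depth_profiles.tsv", cfg, "analyze")
        artifacts["correlations"] = out / "correlations.tsv"
        artifacts["correlation_depth_profiles"] = out / "correlation_depth_profiles.tsv"
        log.info("analyze stage: %d sweeps summarized (%.1fs)", len(sweeps), time.perf_counter() - t0)

    return artifacts
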