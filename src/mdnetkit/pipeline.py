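"""Free-vs-bound comparison pipeline.

Runs the full analysis workflow on a pair of conditions (ligand-free and
ligand-bound, one or two replicate runs each): read → select → window →
geometry metrics (RMSD, RMSF, Rg, interdomain COM distance) → essential
dynamics (covariance trace, eigenvalues, free-energy landscape) → dynamic
residue network (averaged L/BC profiles, hub sets, free−bound deltas, joint
normalisation, Pearson comparisons), then writes every table as CSV plus a
JSON manifest.  Outputs are deterministic for a given config: a rerun
produces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import drn as drn_mod
from . import essential_dynamics as ed
from . import geometry_metrics as gm
from . import trajectory_io as tio

__all__ = ["RunConfig", "CompareReport", "run_compare_pipeline",
           "write_report_tables", "PipelineError"]

logger = logging.getLogger("mdnetkit.pipeline")

FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Declarative configuration of one free-vs-bound comparison."""

    free_paths: list[str]
    bound_paths: list[str]
    selection_scheme: str = "CB_with_CA_for_GLY"
    cutoff: float = drn_mod.DEFAULT_CUTOFF  # Å
    window_fraction: float = 0.15  # analyse the last fraction of each run
    stride_ps: float | None = 10.0
    hub_ksd: dict = field(default_factory=lambda: {"L": 1.0, "BC": 2.0})
    temperature: float = 300.0  # K
    fel_bins: tuple[int, int] = (32, 32)
    dt: float = 2.0  # ps, for PDB inputs without times
    com_chains_a: list[str] | None = None  # e.g. ["A"] — skip COM if unset
    com_chains_b: list[str] | None = None
    units: str = "angstrom"  # or "nm" for reported lengths
    seed: int = 0
    outdir: str = "mdnetkit_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "fel_bins" in raw:
            raw["fel_bins"] = tuple(raw["fel_bins"])
        return cls(**raw)

    def validate(self) -> None:
        if not self.free_paths or not self.bound_paths:
            raise ValueError("need at least one free and one bound trajectory")
        for p in [*self.free_paths, *self.bound_paths]:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        for k, v in self.hub_ksd.items():
            if v <= 0:
                raise ValueError(f"hub k_sd for {k} must be positive")

    def digest(self) -> str:
        payload = {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)}
        payload["fel_bins"] = list(self.fel_bins)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ConditionResult:
    """Per-condition (free or bound) analysis artifacts, runs combined."""

    name: str
    drn: drn_mod.DRNProfile
    rmsf: gm.ResidueProfile
    rmsd: list[gm.SeriesMetric]
    rg: list[gm.SeriesMetric]
    com_distance: list[gm.SeriesMetric] | None
    trace: list[float]  # per-run covariance trace, Å²
    eigenvalues: list[np.ndarray]
    fel: list[ed.FELGrid]
    per_run_drn: list[drn_mod.DRNProfile]


@dataclass
class CompareReport:
    config: RunConfig
    free: ConditionResult
    bound: ConditionResult
    delta_L: drn_mod.DeltaProfile
    delta_BC: drn_mod.DeltaProfile
    norm_L: drn_mod.NormalizedPair
    norm_BC: drn_mod.NormalizedPair
    hubs: list[drn_mod.HubSet]
    correlations: list[dict]
    manifest: dict


def _load_trajectory(path: str, dt: float) -> tio.Trajectory:
    p = Path(path)
    if p.suffix in (".xyzt", ".txt"):
        return tio.read_xyzt(p)
    return tio.read_multimodel_pdb(p, dt=dt)


def _chain_selection(sel: tio.Selection, chains: list[str]) -> tio.Selection:
    keep = [i for i, lab in enumerate(sel.residue_labels) if lab[0] in chains]
    if not keep:
        raise ValueError(f"no residues on chains {chains}")
    return tio.Selection(
        [sel.indices[i] for i in keep],
        [sel.residue_labels[i] for i in keep],
        [sel.masses[i] for i in keep],
    )


def _analyse_condition(name: str, paths: list[str], cfg: RunConfig) -> ConditionResult:
    per_run_drn, rmsds, rgs, coms, traces, eigs, fels = [], [], [], [], [], [], []
    rmsf_profiles = []
    for run_i, path in enumerate(paths):
        logger.info("[%s] run %d: reading %s", name, run_i + 1, path)
        traj = _load_trajectory(path, cfg.dt)
        sel = tio.select_representatives(traj, cfg.selection_scheme)
        window = tio.last_fraction_window(traj, cfg.window_fraction, cfg.stride_ps)

        logger.info("[%s] run %d: geometry metrics", name, run_i + 1)
        rmsf_profiles.append(gm.rmsf_per_residue(traj, sel, fit=True))
        rmsds.append(gm.rmsd_series(traj, traj.frames[0], sel, fit=True))
        rgs.append(gm.rg_series(traj, sel))
        if cfg.com_chains_a and cfg.com_chains_b:
            sa = _chain_selection(sel, cfg.com_chains_a)
            sb = _chain_selection(sel, cfg.com_chains_b)
            coms.append(gm.com_distance_series(traj, sa, sb))

        logger.info("[%s] run %d: essential dynamics", name, run_i + 1)
        cov = ed.build_covariance(traj, sel, fit=True)
        eig = ed.eigendecompose(cov)
        traces.append(eig.trace)
        eigs.append(eig.eigenvalues)
        proj = ed.project_frames(traj, sel, eig, k=2, cov=cov)
        fels.append(ed.fel_from_projections(proj, cfg.fel_bins, cfg.temperature))

        logger.info("[%s] run %d: DRN over %d frames", name, run_i + 1, len(window))
        per_run_drn.append(
            drn_mod.average_profiles(traj, sel, cfg.cutoff, window=window)
        )
    combined = drn_mod.combine_runs(per_run_drn)
    rmsf = gm.ResidueProfile(
        rmsf_profiles[0].residue_labels,
        np.mean([p.values for p in rmsf_profiles], axis=0),
        name="rmsf",
    )
    return ConditionResult(
        name=name, drn=combined, rmsf=rmsf, rmsd=rmsds, rg=rgs,
        com_distance=coms or None, trace=traces, eigenvalues=eigs,
        fel=fels, per_run_drn=per_run_drn,
    )


def run_compare_pipeline(config: RunConfig) -> CompareReport:
    """Execute the full free-vs-bound workflow described by ``config``."""
    try:
        config.validate()
    except Exception as exc:
        raise PipelineError(f"config validation failed: {exc}") from exc

    def stage(fn, label, *args):
        try:
            return fn(*args)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage '{label}' failed: {exc}") from exc

    free = stage(_analyse_condition, "analyse free", "free", config.free_paths, config)
    bound = stage(
        _analyse_condition, "analyse bound", "bound", config.bound_paths, config
    )

    delta_L = stage(drn_mod.delta_profile, "delta L", free.drn, bound.drn, "L")
    delta_BC = stage(drn_mod.delta_profile, "delta BC", free.drn, bound.drn, "BC")
    norm_L = stage(
        drn_mod.joint_minmax_normalize, "normalize L", free.drn.avg_L, bound.drn.avg_L
    )
    norm_BC = stage(
        drn_mod.joint_minmax_normalize, "normalize BC",
        free.drn.avg_BC, bound.drn.avg_BC,
    )

    hubs = []
    for cond in (free, bound):
        hubs.append(drn_mod.detect_hubs(
            cond.drn.profile("L"), config.hub_ksd.get("L", 1.0), "low",
            metric=f"{cond.name}_avg_L"))
        hubs.append(drn_mod.detect_hubs(
            cond.drn.profile("BC"), config.hub_ksd.get("BC", 2.0), "high",
            metric=f"{cond.name}_avg_BC"))

    correlations = []
    for cond in (free, bound):
        pairs = [
            ("avg_L", cond.drn.avg_L, "identity", "rmsf", cond.rmsf.values, "identity"),
            ("avg_L", cond.drn.avg_L, "inverse", "avg_BC", cond.drn.avg_BC, "identity"),
            ("rmsf", cond.rmsf.values, "inverse", "avg_BC", cond.drn.avg_BC, "identity"),
        ]
        for xn, xv, tx, yn, yv, ty in pairs:
            try:
                res = drn_mod.pearson_compare(xv, yv, tx, ty)
            except ValueError as exc:
                logger.warning("correlation %s vs %s skipped: %s", xn, yn, exc)
                continue
            correlations.append({
                "condition": cond.name,
                "x": xn, "transform_x": tx, "y": yn, "transform_y": ty,
                "n_used": res.n_used, "n_excluded": res.n_excluded,
                "r": res.r,
            })

    manifest = {
        "package": "mdnetkit",
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_residues": len(free.drn.residue_labels),
        "dropped_labels_free": [list(l) for l in delta_L.dropped_free],
        "dropped_labels_bound": [list(l) for l in delta_L.dropped_bound],
        "n_frames_drn": {"free": free.drn.n_frames, "bound": bound.drn.n_frames},
    }
    return CompareReport(
        config=config, free=free, bound=bound,
        delta_L=delta_L, delta_BC=delta_BC,
        norm_L=norm_L, norm_BC=norm_BC,
        hubs=hubs, correlations=correlations, manifest=manifest,
    )


def _length_scale(units: str) -> float:
    return 0.1 if units == "nm" else 1.0


def write_report_tables(report: CompareReport, outdir: str | Path) -> dict:
    """Write the report as CSV tables plus a JSON manifest.

    Floats are rendered with 6 significant digits, so reruns of the same
    config produce byte-identical files.  Returns the file manifest.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = report.config
    s = _length_scale(cfg.units)
    files = []

    def write_df(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format=FLOAT_FMT)
        files.append(name)

    labels = report.delta_L.residue_labels
    free_map = {l: i for i, l in enumerate(report.free.drn.residue_labels)}
    bound_map = {l: i for i, l in enumerate(report.bound.drn.residue_labels)}
    fi = [free_map[l] for l in labels]
    bi = [bound_map[l] for l in labels]
    per_res = pd.DataFrame({
        "chain": [l[0] for l in labels],
        "resid": [l[1] for l in labels],
        "resname": [l[2] for l in labels],
        "free_avg_L": report.free.drn.avg_L[fi],
        "free_sd_L": report.free.drn.sd_L[fi],
        "free_avg_BC": report.free.drn.avg_BC[fi],
        "free_sd_BC": report.free.drn.sd_BC[fi],
        "free_rmsf": report.free.rmsf.values[fi] * s,
        "free_reachable_frac": 1 - report.free.drn.unreachable_fraction[fi],
        "bound_avg_L": report.bound.drn.avg_L[bi],
        "bound_sd_L": report.bound.drn.sd_L[bi],
        "bound_avg_BC": report.bound.drn.avg_BC[bi],
        "bound_sd_BC": report.bound.drn.sd_BC[bi],
        "bound_rmsf": report.bound.rmsf.values[bi] * s,
        "bound_reachable_frac": 1 - report.bound.drn.unreachable_fraction[bi],
        "delta_L": report.delta_L.values,
        "delta_BC": report.delta_BC.values,
        "znorm_free_L": report.norm_L.Z_A[fi],
        "znorm_bound_L": report.norm_L.Z_B[bi],
        "znorm_free_BC": report.norm_BC.Z_A[fi],
        "znorm_bound_BC": report.norm_BC.Z_B[bi],
    })
    write_df(per_res, "per_residue.csv")

    hub_rows = [
        {
            "metric": h.metric, "direction": h.direction, "k_sd": h.k_sd,
            "threshold": h.threshold,
            "chain": m[0], "resid": m[1], "resname": m[2],
        }
        for h in report.hubs for m in h.members
    ]
    write_df(
        pd.DataFrame(
            hub_rows,
            columns=["metric", "direction", "k_sd", "threshold",
                     "chain", "resid", "resname"],
        ),
        "hubs.csv",
    )

    write_df(pd.DataFrame(report.correlations,
                          columns=["condition", "x", "transform_x", "y",
                                   "transform_y", "n_used", "n_excluded", "r"]),
             "correlations.csv")

    for cond in (report.free, report.bound):
        for run_i, series_set in enumerate(zip(cond.rmsd, cond.rg)):
            rmsd, rg = series_set
            df = pd.DataFrame({
                "time_ps": rmsd.times,
                "rmsd": rmsd.values * s,
                "rg": rg.values * s,
            })
            if cond.com_distance:
                df["com_distance"] = cond.com_distance[run_i].values * s
            write_df(df, f"series_{cond.name}_run{run_i + 1}.csv")
        eig_rows = []
        for run_i, vals in enumerate(cond.eigenvalues):
            pct = 100 * vals / vals.sum() if vals.sum() > 0 else vals * 0
            for k in range(min(len(vals), 10)):
                eig_rows.append({
                    "run": run_i + 1, "index": k + 1,
                    "eigenvalue": vals[k] * s * s,
                    "percent_variance": pct[k],
                })
        write_df(pd.DataFrame(eig_rows), f"eigenvalues_{cond.name}.csv")
        trace_df = pd.DataFrame({
            "run": np.arange(1, len(cond.trace) + 1),
            "trace": np.asarray(cond.trace) * s * s,
        })
        write_df(trace_df, f"trace_{cond.name}.csv")
        for run_i, grid in enumerate(cond.fel):
            c1 = 0.5 * (grid.pc1_edges[:-1] + grid.pc1_edges[1:])
            c2 = 0.5 * (grid.pc2_edges[:-1] + grid.pc2_edges[1:])
            i_idx, j_idx = np.meshgrid(
                np.arange(len(c1)), np.arange(len(c2)), indexing="ij"
            )
            write_df(pd.DataFrame({
                "pc1_center": c1[i_idx.ravel()] * s,
                "pc2_center": c2[j_idx.ravel()] * s,
                "count": grid.counts.ravel().astype(int),
                "delta_g_kj_mol": grid.delta_g.ravel(),
            }), f"fel_{cond.name}_run{run_i + 1}.csv")

    manifest = dict(report.manifest)
    manifest["files"] = sorted(files)
    manifest["units"] = cfg.units
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("mdnetkit")
    root.handlers[:] = [handler]
    root.setLevel(logging.INFO if verbose else logging.WARNING)
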