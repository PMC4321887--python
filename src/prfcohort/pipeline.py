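"""Pipeline orchestration: simulate → fit → measure → analyze → report.

A ``RunConfig`` (YAML/JSON, fully defaulted) drives the five stages; a
master seed spawns independent sub-seeds per stage, so a rerun with the
same config reproduces every stochastic output bit-identically.  All
tables are TSV (UTF-8, '.' decimal), summaries and provenance JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import typing
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anatomy as anat
from . import stats as st
from .prf import (
    HRFParams,
    PRFFitter,
    PRFParams,
    SearchConfig,
    StimulusConfig,
    make_bar_stimulus,
    simulate_bold,
)
from .psychophysics import (
    PsychometricObserver,
    StaircaseConfig,
    ThresholdMap,
    measure_thresholds,
    project_to_cortex,
    write_threshold_map,
    write_tracks,
)
from .synthetic_cohort import (
    Cohort,
    CohortConfig,
    generate_cohort,
    read_vertex_table,
    write_anatomy_json,
    write_vertex_table,
)

__all__ = ["RunConfig", "ReportBundle", "StageError", "run_pipeline",
           "load_config", "config_hash"]

log = logging.getLogger("prfcohort")

_pkg_version = "0.1.0"


class StageError(RuntimeError):
    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Full run configuration; every field has a usable default."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    hrf: HRFParams = field(default_factory=HRFParams)
    search: SearchConfig = field(default_factory=SearchConfig)
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)

    prf_noise_sd: float = 1.0  # BOLD noise; amplitude 1 -> SNR 1
    prf_fit_voxels: int = 12  # fitted vertices per participant (first area)
    n_perm: int = 10000
    fixed_ecc: float = 4.7
    fixed_ecc_tol: float = 0.5
    n_ecc_bins: int = 10
    thickness_bin_width: float = 0.1
    value_col: str = "true_sigma"  # width column for the analyses
    write_tracks: bool = True
    seed: int = 0  # master seed; overrides cohort.seed


def _hydrate(cls, data):
    """Build a (possibly nested) dataclass from a plain dict."""
    if data is None:
        return cls()
    if dataclasses.is_dataclass(cls):
        hints = typing.get_type_hints(cls)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            val = data[f.name]
            hint = hints.get(f.name, f.type)
            if dataclasses.is_dataclass(hint) and isinstance(val, dict):
                val = _hydrate(hint, val)
            elif typing.get_origin(hint) is tuple and isinstance(
                val, (list, tuple)
            ):
                val = tuple(val)
            kwargs[f.name] = val
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(
                f"unknown {cls.__name__} fields: {sorted(unknown)}"
            )
        return cls(**kwargs)
    return data


def load_config(path=None, overrides=None) -> RunConfig:
    """Load a YAML/JSON run configuration with full defaulting.

    ``overrides`` is a flat dict of top-level RunConfig fields (CLI flags),
    except ``n_participants`` which is routed into the cohort config.
    """
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("config root must be a mapping")
    if overrides:
        overrides = dict(overrides)
        n_part = overrides.pop("n_participants", None)
        if n_part is not None:
            data.setdefault("cohort", {})
            data["cohort"]["n_participants"] = n_part
        for k, v in overrides.items():
            if v is not None:
                data[k] = v
    return _hydrate(RunConfig, data)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True,
                         default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seeds(master):
    """Four independent 31-bit stage seeds from the master seed."""
    state = np.random.SeedSequence(master).generate_state(4, np.uint64)
    return [int(s & 0x7FFFFFFF) for s in state]


@dataclass
class ReportBundle:
    """All report sections plus provenance; serializable to JSON."""

    anatomy_summary: pd.DataFrame
    contrasts: pd.DataFrame
    fixed_ecc: dict  # area -> FixedEccentricityResult
    ecc_resolved: pd.DataFrame  # long-format correlation table
    recovery: pd.DataFrame
    thresholds: pd.DataFrame
    provenance: dict

    def summary(self) -> dict:
        rec = self.recovery
        out = {
            "provenance": self.provenance,
            "coverage_fraction_mean": float(
                self.anatomy_summary["coverage_fraction"].mean()
            ),
            "thickness_fit_mean_mm": float(
                self.anatomy_summary["thickness_mean_fit"].mean()
            ),
            "sigma_recovery_median_rel_err": (
                float(
                    np.median(
                        np.abs(rec["fitted_sigma"] - rec["true_sigma"])
                        / rec["true_sigma"]
                    )
                )
                if len(rec)
                else None
            ),
            "contrasts": self.contrasts.to_dict(orient="records"),
            "fixed_eccentricity": {
                area: st.correlation_table(res.results).to_dict(
                    orient="records"
                )
                for area, res in self.fixed_ecc.items()
            },
            "eccentricity_resolved": self.ecc_resolved.to_dict(
                orient="records"
            ),
        }
        return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, out_dir=None) -> Cohort:
    cohort_cfg = dataclasses.replace(
        config.cohort, seed=_stage_seeds(config.seed)[0]
    )
    cohort = generate_cohort(cohort_cfg)
    log.info(
        "simulated cohort: %d participants, %d vertices",
        cohort_cfg.n_participants, len(cohort.vertices),
    )
    if out_dir:
        out = Path(out_dir)
        write_vertex_table(cohort.vertices, out / "vertices.tsv")
        write_anatomy_json(cohort.anatomy, cohort_cfg, out / "anatomy.json")
        _write_observers(cohort.observers, out / "observers.json")
    return cohort


def stage_prf_fit(config: RunConfig, cohort: Cohort, out_dir=None):
    """Simulate + refit BOLD for a per-participant subsample of vertices.

    Appends fitted_x0/fitted_y0/fitted_sigma/fitted_r2 columns (NaN outside
    the subsample) and returns the recovery table.
    """
    seed = _stage_seeds(config.seed)[1]
    rng = np.random.default_rng(seed)
    stim = make_bar_stimulus(config.stimulus)
    fitter = PRFFitter(stim, config.hrf, config.search)
    area = config.cohort.areas[0]
    v = cohort.vertices
    for col in ("fitted_x0", "fitted_y0", "fitted_sigma", "fitted_r2"):
        v[col] = np.nan

    rows = []
    for pid in cohort.participant_ids():
        pool = v.index[
            (v["participant_id"] == pid)
            & (v["area"] == area)
            & (v["eccentricity"] <= config.stimulus.ecc_max - 0.3)
        ].to_numpy()
        if pool.size == 0:
            continue
        pick = rng.choice(
            pool, size=min(config.prf_fit_voxels, pool.size), replace=False
        )
        for idx in pick:
            row = v.loc[idx]
            th = np.deg2rad(row["polar_angle"])
            prf = PRFParams(
                x0=row["eccentricity"] * np.cos(th),
                y0=row["eccentricity"] * np.sin(th),
                sigma=max(row["true_sigma"], 0.05),
            )
            series = simulate_bold(
                prf, stim, config.hrf, config.prf_noise_sd, rng
            )
            est = fitter.fit(series)
            v.loc[idx, ["fitted_x0", "fitted_y0", "fitted_sigma",
                        "fitted_r2"]] = [est.x0, est.y0, est.sigma,
                                         est.goodness_of_fit]
            rows.append(
                {
                    "participant_id": pid,
                    "vertex_id": int(row["vertex_id"]),
                    "true_sigma": prf.sigma,
                    "fitted_sigma": est.sigma,
                    "true_ecc": prf.eccentricity,
                    "fitted_ecc": est.eccentricity,
                    "r2": est.goodness_of_fit,
                }
            )
    recovery = pd.DataFrame(rows)
    if len(recovery):
        med = np.median(
            np.abs(recovery["fitted_sigma"] - recovery["true_sigma"])
            / recovery["true_sigma"]
        )
        log.info("pRF recovery: median relative sigma error %.3f", med)
    if out_dir:
        out = Path(out_dir)
        write_vertex_table(v, out / "vertices_fitted.tsv")
        recovery.to_csv(out / "prf_recovery.tsv", sep="\t", index=False)
    return recovery


def stage_psychophysics(config: RunConfig, cohort: Cohort, out_dir=None):
    """Run the 13 staircases per participant; returns threshold maps."""
    seed = _stage_seeds(config.seed)[2]
    rngs = np.random.SeedSequence(seed).spawn(len(cohort.observers))
    maps: dict[str, ThresholdMap] = {}
    all_tracks = []
    for (pid, obs_list), ss in zip(sorted(cohort.observers.items()), rngs):
        tmap, tracks = measure_thresholds(
            obs_list, config.staircase, np.random.default_rng(ss),
            participant_id=pid, return_tracks=True,
        )
        maps[pid] = tmap
        if out_dir and config.write_tracks:
            all_tracks.append((pid, tracks))
    if out_dir:
        out = Path(out_dir)
        combined = pd.concat(
            [
                m.table.assign(participant_id=pid)
                for pid, m in maps.items()
            ],
            ignore_index=True,
        )
        combined.to_csv(out / "thresholds.tsv", sep="\t", index=False)
        for pid, tracks in all_tracks:
            write_tracks(tracks, out / f"tracks_{pid}.tsv")
    return maps


def stage_analyze(config: RunConfig, cohort: Cohort, threshold_maps,
                  out_dir=None):
    seed = _stage_seeds(config.seed)[3]
    rng = np.random.default_rng(seed)
    v = cohort.vertices
    cfg = config

    # anatomy summaries (coverage, thickness fit, surface area)
    summary_rows = []
    for a in cohort.anatomy:
        for area in cfg.cohort.areas:
            sel = v[(v["participant_id"] == a.participant_id)
                    & (v["area"] == area)]
            efit = anat.fit_exponential(
                sel["eccentricity"], coverage_range=cfg.cohort.ecc_range
            )
            gfit = anat.fit_gaussian(sel["thickness"])
            summary_rows.append(
                {
                    "participant_id": a.participant_id,
                    "area": area,
                    "surface_area": a.surface_area[area],
                    "decay_b": efit.b,
                    "coverage_fraction": efit.coverage_fraction,
                    "thickness_mean_fit": gfit.mean,
                    "thickness_sd_fit": gfit.sd,
                }
            )
    summary = pd.DataFrame(summary_rows)

    contrast_rows = []
    for area in cfg.cohort.areas:
        for name, c in anat.folding_eccentricity_contrast(
            v, area=area
        ).items():
            contrast_rows.append(
                {"area": area, "contrast": name, "T": c.T, "p": c.p,
                 "n": c.n}
            )
    contrasts = pd.DataFrame(contrast_rows)

    value_col = cfg.value_col
    if value_col not in v.columns:
        raise StageError("analyze", f"missing width column {value_col!r}")

    fixed = {}
    ecc_rows = []
    for area in cfg.cohort.areas:
        areas_by_pid = {
            a.participant_id: a.surface_area[area] for a in cohort.anatomy
        }
        fixed[area] = st.fixed_eccentricity_analysis(
            v, threshold_maps, areas_by_pid, area=area,
            value_col=value_col, ecc=cfg.fixed_ecc, tol=cfg.fixed_ecc_tol,
            n_perm=cfg.n_perm, rng=rng,
        )
        # width grids: participant axis vs surface area, thickness axis
        for axis2, anat_vals in (
            ("participant", areas_by_pid),
            ("thickness", None),
        ):
            grid = st.build_grid(
                v, value_col, axis2=axis2, n_ecc_bins=cfg.n_ecc_bins,
                thickness_bin_width=cfg.thickness_bin_width, area=area,
            )
            res = st.eccentricity_resolved_analysis(
                grid, anat_vals, n_perm=cfg.n_perm, rng=rng
            )
            for r in res.results:
                ecc_rows.append(
                    {"area": area, "value": "width", "axis2": axis2,
                     "family": r.family, "pair": r.pair, "rho": r.rho,
                     "p_raw": r.p_raw, "p_fwe": r.p_fwe, "n": r.n}
                )
        # threshold grids from the cortical projection
        proj = []
        for pid, tmap in threshold_maps.items():
            sel = v[(v["participant_id"] == pid) & (v["area"] == area)]
            p = project_to_cortex(tmap, sel)
            proj.append(sel.assign(threshold=p["threshold"].to_numpy()))
        vt = pd.concat(proj, ignore_index=True)
        for axis2, anat_vals in (
            ("participant", areas_by_pid),
            ("thickness", None),
        ):
            grid = st.build_grid(
                vt, "threshold", axis2=axis2, n_ecc_bins=cfg.n_ecc_bins,
                thickness_bin_width=cfg.thickness_bin_width,
            )
            res = st.eccentricity_resolved_analysis(
                grid, anat_vals, n_perm=cfg.n_perm, rng=rng
            )
            for r in res.results:
                ecc_rows.append(
                    {"area": area, "value": "threshold", "axis2": axis2,
                     "family": r.family, "pair": r.pair, "rho": r.rho,
                     "p_raw": r.p_raw, "p_fwe": r.p_fwe, "n": r.n}
                )
    ecc_resolved = pd.DataFrame(ecc_rows)

    if out_dir:
        out = Path(out_dir)
        summary.to_csv(out / "anatomy_summary.tsv", sep="\t", index=False)
        contrasts.to_csv(out / "contrasts.tsv", sep="\t", index=False)
        for area, res in fixed.items():
            st.correlation_table(res.results).to_csv(
                out / f"fixed_ecc_correlations_{area}.tsv", sep="\t",
                index=False,
            )
            res.table.to_csv(
                out / f"fixed_ecc_table_{area}.tsv", sep="\t", index=False
            )
        ecc_resolved.to_csv(
            out / "ecc_resolved_correlations.tsv", sep="\t", index=False
        )
    return summary, contrasts, fixed, ecc_resolved


def run_pipeline(config: RunConfig, out_dir=None) -> ReportBundle:
    """Execute all stages in order; writes every intermediate when
    ``out_dir`` is given.  Any stage failure aborts with a stage-tagged
    error and a partial-output manifest."""
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(out / "run.log")
        fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(fh)
    stage = "simulate"
    try:
        cohort = stage_simulate(config, out)
        stage = "prf-fit"
        recovery = stage_prf_fit(config, cohort, out)
        stage = "psychophysics"
        maps = stage_psychophysics(config, cohort, out)
        stage = "analyze"
        summary, contrasts, fixed, ecc_resolved = stage_analyze(
            config, cohort, maps, out
        )
        stage = "report"
        thresholds = pd.concat(
            [m.table.assign(participant_id=pid) for pid, m in maps.items()],
            ignore_index=True,
        )
        bundle = ReportBundle(
            anatomy_summary=summary,
            contrasts=contrasts,
            fixed_ecc=fixed,
            ecc_resolved=ecc_resolved,
            recovery=recovery,
            thresholds=thresholds,
            provenance={
                "config_hash": config_hash(config),
                "master_seed": config.seed,
                "stage_seeds": _stage_seeds(config.seed),
                "version": _pkg_version,
            },
        )
        if out:
            (out / "report.json").write_text(
                json.dumps(bundle.summary(), indent=2, default=float)
            )
        return bundle
    except Exception as exc:
        if out:
            manifest = sorted(p.name for p in out.iterdir())
            (out / "manifest_partial.json").write_text(
                json.dumps({"failed_stage": stage, "files": manifest},
                           indent=2)
            )
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, str(exc)) from exc
    finally:
        if out_dir is not None:
            log.removeHandler(fh)
            fh.close()


def _write_observers(observers, path):
    payload = {
        pid: [
            {
                "position": list(o.position),
                "alpha": o.alpha,
                "beta": o.beta,
                "gamma": o.gamma,
                "lapse": o.lapse,
            }
            for o in obs_list
        ]
        for pid, obs_list in observers.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_observers(path):
    payload = json.loads(Path(path).read_text())
    return {
        pid: [
            PsychometricObserver(
                position=tuple(o["position"]), alpha=o["alpha"],
                beta=o["beta"], gamma=o["gamma"], lapse=o["lapse"],
            )
            for o in obs_list
        ]
        for pid, obs_list in payload.items()
    }
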