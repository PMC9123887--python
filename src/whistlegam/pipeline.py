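"""File-driven pipeline: ingest → covariates → circular tests → global GAM →
clustering → grouped models → contrasts.

Stages communicate through CSV/JSON files in the output directory, so any
stage can be re-run independently.  A manifest records the configuration
hash, the seeds consumed and a checksum per output file; deterministic
stages are bit-identical under the same config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import circular as circ
from . import clustering as clus
from . import covariates as cov
from . import gam, hgam, ingest, synth
from .errors import ConfigError, WhistlegamError

SCHEMA_VERSION = "1"


class StageError(WhistlegamError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """One config drives the whole analysis.

    Exactly one of ``synthetic`` (preset parameters) or ``inputs`` (paths to
    real whistle log / schedule / tide / SST / Chl tables) must be set.
    """

    outdir: str = "out"
    seed: int = 0
    synthetic: dict | None = None
    inputs: dict | None = None
    lat: float = synth.SITE_LAT
    lon: float = synth.SITE_LON
    timezone: str = "local"
    screening_cutoff: float = 0.7
    screening_priority: list = field(
        default_factory=lambda: ["sst", "moon", "tide", "dtide", "hour", "daylength",
                                 "depth", "distance", "flow", "delta_sst", "chl"]
    )
    env_variables: list = field(default_factory=lambda: ["sst", "chl", "daylength"])
    gam_k: dict = field(default_factory=lambda: {"hour": 8, "moon": 8, "sst": 8,
                                                 "depth": 4, "distance": 4, "tensor": 4})
    gam_criterion: str = "reml"
    gam_maxfev: int | None = None
    forward_selection: bool = False
    cluster_k: int | None = None
    cluster_threshold: float = 0.70
    contrast_grid: int = 200
    contrast_level: float = 0.95
    grouped_variables: list = field(default_factory=lambda: ["hour"])
    n_perm: int = 1999
    n_boot: int = 200

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True, default=str).encode()).hexdigest()[:16]


def validate_config(config: PipelineConfig) -> list[str]:
    """Empty list iff the config is runnable; each issue names the field."""
    issues = []
    if (config.synthetic is None) == (config.inputs is None):
        issues.append("synthetic/inputs: exactly one of the synthetic preset or real input paths must be set")
    if not (0.0 < config.screening_cutoff <= 1.0):
        issues.append(f"screening_cutoff: must be in (0, 1], got {config.screening_cutoff}")
    if config.gam_criterion not in ("reml", "gcv"):
        issues.append(f"gam_criterion: must be 'reml' or 'gcv', got {config.gam_criterion!r}")
    if not (0.5 <= config.contrast_level < 1.0):
        issues.append(f"contrast_level: must be in [0.5, 1), got {config.contrast_level}")
    if config.inputs is not None:
        for key, p in config.inputs.items():
            if not Path(p).exists():
                issues.append(f"inputs.{key}: path {p} does not exist")
    return issues


def _seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=str) + "\n")


# ---------------------------------------------------------------------------
# stages


def stage_data(config: PipelineConfig, out: Path) -> None:
    """Materialize input tables (synthetic preset or normalized real files)."""
    if config.synthetic is not None:
        s_sched, s_forc, s_sim, s_ev = _seeds(config.seed, 4)
        kwargs = dict(config.synthetic)
        truth_kwargs = {k: kwargs.pop(k) for k in ("hour_amplitudes", "sst_strength") if k in kwargs}
        schedule = synth.make_schedule(seed=s_sched, **kwargs)
        forcings = synth.make_forcings(schedule, seed=s_forc)
        truth = synth.default_truth(seed=s_sim, **truth_kwargs)
        records = synth.simulate_dp10m(schedule, forcings, truth, seed=s_sim)
        events = synth.simulate_whistles(records, schedule, seed=s_ev)
        pd.DataFrame(
            [
                {
                    "deployment_id": w.deployment_id, "station_id": w.station_id,
                    "start": w.start.isoformat(), "end": w.end.isoformat(),
                    "depth_m": w.depth_m, "distance_km": w.distance_km,
                    "coast_km": w.coast_km, "mangrove_km": w.mangrove_km, "bottom": w.bottom,
                }
                for w in schedule
            ]
        ).to_csv(out / "schedule.csv", index=False)
        pd.DataFrame(
            [{"timestamp": e.timestamp.isoformat(), "deployment_id": e.deployment_id,
              "station_id": e.station_id} for e in events]
        ).to_csv(out / "whistles.csv", index=False)
        forcings.tide_series.rename_axis("datetime").reset_index().to_csv(out / "tide.csv", index=False)
        forcings.sst_table.to_csv(out / "sst.csv", index=False)
        forcings.sst_bay_table.to_csv(out / "sst_bay.csv", index=False)
        forcings.chl_table.to_csv(out / "chl.csv", index=False)
        with open(out / "truth.yaml", "w") as fh:
            yaml.safe_dump(
                {"beta0": truth.beta0, "effort_slope": truth.effort_slope,
                 "seeds": {"schedule": s_sched, "forcings": s_forc, "simulation": s_sim,
                           "events": s_ev}},
                fh,
            )
    else:
        for key, name in [("whistles", "whistles.csv"), ("schedule", "schedule.csv"),
                          ("tide", "tide.csv"), ("sst", "sst.csv"),
                          ("sst_bay", "sst_bay.csv"), ("chl", "chl.csv")]:
            if key in config.inputs:
                pd.read_csv(config.inputs[key]).to_csv(out / name, index=False)


def stage_ingest(config: PipelineConfig, out: Path) -> None:
    events = ingest.load_whistle_log(out / "whistles.csv")
    schedule = ingest.load_schedule(out / "schedule.csv")
    records = ingest.bin_dp10m(events, schedule)
    ingest.save_dp10m_table(records, out / "hourly.csv")
    s = ingest.summarize_effort(records)
    _write_json(
        out / "effort_summary.json",
        {"total_hours": s.total_hours, "positive_hours": s.positive_hours,
         "total_bins": s.total_bins, "positive_bins": s.positive_bins},
    )
    s.per_deployment.to_csv(out / "effort_by_deployment.csv", index=False)


def stage_covariates(config: PipelineConfig, out: Path) -> None:
    records = ingest.load_dp10m_table(out / "hourly.csv")
    schedule = ingest.load_schedule(out / "schedule.csv")
    tide_df = pd.read_csv(out / "tide.csv", parse_dates=["datetime"])
    tide_series = pd.Series(tide_df["height_m"].to_numpy(), index=tide_df["datetime"])
    cov.attach_cyclic(records, tide_series, config.lat, config.lon)
    cov.attach_environment(
        records, pd.read_csv(out / "sst.csv"), pd.read_csv(out / "sst_bay.csv"),
        pd.read_csv(out / "chl.csv"),
    )
    cov.attach_static(records, schedule)
    frame = ingest.records_to_frame(records)
    frame.to_csv(out / "hourly_covariates.csv", index=False)
    numeric = ["moon", "tide", "flow", "dtide", "hour", "daylength", "sst",
               "delta_sst", "chl", "depth", "distance", "coast", "mangrove"]
    numeric = [c for c in numeric if c in frame.columns and frame[c].notna().all()]
    screen = cov.spearman_screen(frame[numeric], cutoff=config.screening_cutoff,
                                 priority=config.screening_priority)
    env = frame.groupby("deployment_id")[[v for v in config.env_variables if v in frame]].mean()
    kmo_overall, kmo_per = cov.kmo(env)
    _write_json(
        out / "screening.json",
        {"retained": screen.retained,
         "dropped": [{"variable": d, "partner": p, "rho": r} for d, p, r in screen.dropped],
         "kmo_overall": kmo_overall, "kmo_per_variable": kmo_per.to_dict()},
    )


def stage_circular(config: PipelineConfig, out: Path) -> None:
    frame = pd.read_csv(out / "hourly_covariates.csv")
    pos = frame[frame["dp10m"] > 0]
    s_hr, s_moon, s_map = _seeds(config.seed + 1, 3)
    results = {}
    hour0 = pos["hour"].to_numpy(float) - 0.5  # top of hour
    samples = {
        "hour": circ.CircularSample(circ.dp10m_hour_angles(hour0, pos["dp10m"].to_numpy())),
        "moon": circ.CircularSample(circ.fractions_to_angles(pos["moon"]), pos["dp10m"].to_numpy()),
    }
    for name, sample, sd in [("hour", samples["hour"], s_hr), ("moon", samples["moon"], s_moon)]:
        T, p = circ.hermans_rasson(sample, n_perm=config.n_perm, seed=sd)
        results[name] = {"T": T, "p": p, "n": sample.n_effective}
    _write_json(out / "circular_tests.json", results)
    for name, sample in samples.items():
        m = circ.circsizer(sample, n_boot=config.n_boot, seed=s_map)
        m.to_frame().to_csv(out / f"circsizer_{name}.csv", index=False)


def global_model_spec(frame: pd.DataFrame, k: dict) -> gam.ModelSpec:
    """The nine-variable global model: cyclic moon and hour, thin-plate SST,
    depth and distance, a tide×tide-trend tensor, and linear effort."""
    def kk(name, col):
        return min(k.get(name, 8), max(3, frame[col].nunique() - 1))

    smooths = [
        gam.BasisSpec("cyclic", ("moon",), k=k.get("moon", 8), period=(0.0, 1.0)),
        gam.BasisSpec("cyclic", ("hour",), k=k.get("hour", 8), period=(0.0, 24.0)),
        gam.BasisSpec("thinplate", ("sst",), k=kk("sst", "sst")),
        gam.BasisSpec("thinplate", ("depth",), k=kk("depth", "depth")),
        gam.BasisSpec("thinplate", ("distance",), k=kk("distance", "distance")),
        gam.BasisSpec("tensor", ("dtide", "tide"), k=k.get("tensor", 4)),
    ]
    return gam.ModelSpec(response="dp10m", smooths=smooths, linear=["effort_min"])


def stage_gam(config: PipelineConfig, out: Path) -> None:
    frame = pd.read_csv(out / "hourly_covariates.csv")
    spec = global_model_spec(frame, config.gam_k)
    if config.forward_selection:
        base = gam.ModelSpec(response="dp10m", smooths=[], linear=["effort_min"])
        trace = gam.forward_select(list(spec.smooths), base, frame,
                                   criterion=config.gam_criterion, maxfev=config.gam_maxfev)
        trace.to_frame().to_csv(out / "selection_trace.csv", index=False)
        spec = trace.final_spec
    fitted = gam.fit(spec, frame, criterion=config.gam_criterion, maxfev=config.gam_maxfev)
    summary = fitted.summary()
    shares, excl = [], []
    for label in summary["label"]:
        if label in fitted.design.term_slices and label != "(Intercept)":
            d = gam.deviance_decomposition(fitted, label)
            shares.append(d["share"])
            excl.append(d["dev_explained_excluded"])
        else:
            shares.append(np.nan)
            excl.append(np.nan)
    summary["dev_explained_excluded"] = excl
    summary["rel_deviance_share"] = shares
    summary.to_csv(out / "gam_summary.csv", index=False)
    _write_json(
        out / "gam_meta.json",
        {"aic": fitted.aic, "deviance": fitted.deviance,
         "null_deviance": fitted.null_deviance,
         "deviance_explained": fitted.deviance_explained,
         "edf_total": fitted.edf_total, "n": fitted.n,
         "lambdas": fitted.lambdas, "criterion": fitted.criterion},
    )


def stage_cluster(config: PipelineConfig, out: Path) -> None:
    frame = pd.read_csv(out / "hourly_covariates.csv")
    env_vars = [v for v in config.env_variables if v in frame.columns]
    env = clus.deployment_env_table(frame, env_vars)
    kmo_overall, _ = cov.kmo(env)
    pca_res, assign = clus.hcpc(env, var_threshold=config.cluster_threshold,
                                k=config.cluster_k, seed=config.seed)
    # name clusters by their dominant seasonal block for readability
    frame["month"] = pd.to_datetime(frame["hour_start"]).dt.month
    season = pd.to_datetime(frame["hour_start"]).map(synth.season_of)
    dep_season = pd.DataFrame({"deployment_id": frame["deployment_id"], "season": season})
    names = {}
    for cid in sorted(assign.labels.unique()):
        deps = assign.labels[assign.labels == cid].index
        mode = dep_season[dep_season["deployment_id"].isin(deps)]["season"].mode()
        name = str(mode.iloc[0]) if len(mode) else f"C{cid}"
        while name in names.values():
            name = f"{name}+{cid}"
        names[cid] = name
    labels = assign.labels.map(names)
    labels.rename("cluster").reset_index().to_csv(out / "clusters.csv", index=False)
    frame["cluster"] = frame["deployment_id"].map(labels)
    frame.to_csv(out / "hourly_clustered.csv", index=False)
    tests = {}
    dist = clus.check_distributions(frame["dp10m"].to_numpy(), frame["deployment_id"].to_numpy())
    for grouping in ("deployment_id", "month", "cluster"):
        r = clus.kruskal_nemenyi(frame["dp10m"].to_numpy(), frame[grouping].to_numpy(), grouping)
        tests[grouping] = {"chi2": r.chi2, "df": r.df, "p": r.p,
                           "nemenyi_p": r.nemenyi_p.to_dict()}
    _write_json(out / "rank_tests.json",
                {"distribution_checks": dist, "kruskal_wallis": tests,
                 "kmo_overall": kmo_overall,
                 "pca_cumulative_variance": list(map(float, pca_res.cumulative)),
                 "n_components_retained": pca_res.n_retained,
                 "cluster_sizes": labels.value_counts().to_dict()})


def stage_grouped(config: PipelineConfig, out: Path) -> None:
    frame = pd.read_csv(out / "hourly_clustered.csv")
    base = global_model_spec(frame, config.gam_k)
    rows = []
    contrast_frames = []
    for var in config.grouped_variables:
        fam = hgam.fit_variant_family(base, frame, var, "cluster",
                                      criterion=config.gam_criterion,
                                      maxfev=config.gam_maxfev)
        comp = hgam.compare_grouped(
            fam["G"], {(var, v): f for v, f in fam.items() if v != "G"})
        rows.append(comp)
        for variant in ("S", "I"):
            f = fam[variant]
            term = next(t.label for t in f.design.terms if t.spec.by_group == "cluster")
            levels = next(t for t in f.design.terms if t.spec.by_group == "cluster").levels
            for i, a in enumerate(levels):
                for b in levels[i + 1:]:
                    curve = hgam.smooth_difference(f, term, a, b,
                                                   n_grid=config.contrast_grid,
                                                   level=config.contrast_level)
                    cf = curve.to_frame()
                    cf.insert(0, "variable", var)
                    cf.insert(1, "variant", variant)
                    cf.insert(2, "pair", f"{a} vs {b}")
                    contrast_frames.append(cf)
    pd.concat(rows, ignore_index=True).to_csv(out / "grouped_comparison.csv", index=False)
    pd.concat(contrast_frames, ignore_index=True).to_csv(out / "contrasts.csv", index=False)


STAGES = [
    ("data", stage_data),
    ("ingest", stage_ingest),
    ("covariates", stage_covariates),
    ("circular", stage_circular),
    ("gam", stage_gam),
    ("cluster", stage_cluster),
    ("grouped", stage_grouped),
]


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the pipeline (optionally a subset of stages); returns the manifest."""
    issues = validate_config(config)
    if issues:
        raise ConfigError("; ".join(issues))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, fn in STAGES:
        if stages is not None and name not in stages:
            continue
        try:
            fn(config, out)
        except Exception as exc:  # noqa: BLE001 — re-raise with stage context
            raise StageError(name, exc) from exc
    checksums = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": asdict(config),
        "checksums": checksums,
    }
    _write_json(out / "manifest.json", manifest)
    return manifest
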