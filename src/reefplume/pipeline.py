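"""End-to-end orchestration: tracers -> exposure -> synthetic communities
-> diversity and multivariate statistics -> machine-readable report.

A run is driven by one YAML config (see ``data/default_scenario.yaml``)
and a master seed; every stage's derived seed, output paths and status
are recorded in a JSON manifest so that an identical config and seed
reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import (
    alpha_diversity_table,
    eukaryote_prokaryote_ratio,
    mann_whitney_one_sided,
    rarefy,
)
from .exposure import (
    ExposureParams,
    SiteRecord,
    classify_site,
    exposure_at_dates,
    exposure_map,
    site_exposure_table,
)
from .io import read_biom_json, read_otu_tsv, write_biom_json, write_otu_tsv, write_tsv
from .multivariate import (
    efa,
    hellinger_and_distance,
    pcoa,
    permanova,
    indval,
    pearson_matrix,
    rda,
    stepwise_aic_rda,
)
from .synth import (
    EnvTable,
    ScenarioConfig,
    estimate_riverine_fraction,
    generate_environment,
    generate_otu_table,
    riverine_endmember,
    water_quality_index,
)
from .transport import (
    ConfigError,
    FlowField,
    Grid,
    RiverSource,
    TransportParams,
    run_simulation,
)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "load_config", "default_config_path"]


def default_config_path() -> Path:
    return Path(resources.files("reefplume") / "data" / "default_scenario.yaml")


def load_config(path=None) -> dict:
    """Load and schema-check a scenario config (default bundled scenario)."""
    path = Path(path) if path else default_config_path()
    cfg = yaml.safe_load(path.read_text())
    for block in ("scenario", "exposure", "sites", "synthesis", "analysis"):
        if block not in cfg:
            raise ConfigError(f"config missing block {block!r}")
    return cfg


RunConfig = dict  # structured per data/default_scenario.yaml


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    version: str
    stage_seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    status: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _build_scenario(cfg: dict):
    sc = cfg["scenario"]
    g = sc["grid"]
    mask = np.ones((g["ny"], g["nx"]), dtype=bool)
    mask[: int(g.get("coast_rows", 0)), :] = False
    grid = Grid(nx=g["nx"], ny=g["ny"], dx=g["dx"], dy=g["dy"], mask=mask, depth=g.get("depth", 10.0))
    # river mouths sit on the coast edge: carve them into the land strip
    for r in sc["rivers"]:
        j, i = r["mouth"]
        mask_w = grid.mask.copy()
        mask_w.setflags(write=True)
        mask_w[j, i] = True
        grid = Grid(nx=grid.nx, ny=grid.ny, dx=grid.dx, dy=grid.dy, mask=mask_w, depth=grid.depth)

    f = sc["flow"]
    u = np.where(grid.mask, float(f.get("u", 0.0)), 0.0)
    v = np.where(grid.mask, float(f.get("v", 0.0)), 0.0)
    flow = FlowField(u=u, v=v, description=f.get("description", ""))

    start, end = (pd.Timestamp(t).date() for t in sc["window"])
    season = cfg["exposure"].get("season")
    sources = []
    for r in sc["rivers"]:
        if "hydrograph" in r:
            h = pd.read_csv(r["hydrograph"], sep="\t", parse_dates=["date"]).set_index("date")["ml_d"]
        else:
            days = pd.date_range(start, end, freq="D")
            q = np.full(len(days), float(r.get("baseflow_ml_d", 0.0)))
            if season:
                s0, s1 = (pd.Timestamp(t) for t in season)
                wet = (days >= s0) & (days <= s1)
                q[wet] = float(r.get("wet_flow_ml_d", r.get("baseflow_ml_d", 0.0)))
            h = pd.Series(q, index=days)
        sources.append(RiverSource(name=r["name"], cell=tuple(r["mouth"]), discharge=h))

    p = sc.get("params", {})
    params = TransportParams(
        K=float(p.get("K", 50.0)),
        dt=float(p.get("dt", 600.0)),
        boundary_mode=p.get("boundary_mode", "closed"),
    )
    return grid, flow, sources, params, (start, end)


def _build_sites(cfg: dict) -> list[SiteRecord]:
    sites = []
    for s in cfg["sites"]:
        rec = SiteRecord(
            id=s["id"],
            cell=tuple(s["cell"]) if "cell" in s else None,
            distance_km=float(s["distance_km"]),
            relation=s["relation"],
        )
        rec.category = classify_site(rec)
        sites.append(rec)
    return sites


def run_pipeline(config: dict | str | Path | None = None, outdir="reefplume_run", seed: int = 0) -> RunManifest:
    """Execute all stages in dependency order and write a run manifest.

    When ``synthesis.otu_table`` names an existing BIOM/TSV table, the
    simulation and synthesis stages are skipped and statistics run on the
    external table (metadata must then be supplied as
    ``synthesis.metadata`` TSV with category/season columns).
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    child = {name: int(s.generate_state(1)[0] % (2**31)) for name, s in
             zip(["synthesis", "rarefaction", "permanova", "indval", "rda", "efa"], ss.spawn(6))}
    manifest = RunManifest(config_hash=_config_hash(cfg), master_seed=seed, version=__version__,
                           stage_seeds=child)

    def done(stage, **outs):
        manifest.status[stage] = "ok"
        for k, v in outs.items():
            manifest.outputs[f"{stage}.{k}"] = str(v)

    sites = _build_sites(cfg)
    site_df = pd.DataFrame(
        [{"site_id": s.id, "distance_km": s.distance_km, "relation": s.relation, "category": s.category}
         for s in sites]
    ).set_index("site_id")
    write_tsv(site_df, outdir / "sites.tsv")
    done("classify_sites", table=outdir / "sites.tsv")

    external = cfg["synthesis"].get("otu_table")
    expo_cfg = cfg["exposure"]
    params = ExposureParams(
        threshold_fraction=float(expo_cfg.get("threshold_fraction", 0.01)),
        season_start=pd.Timestamp(expo_cfg["season"][0]).date() if "season" in expo_cfg else None,
        season_end=pd.Timestamp(expo_cfg["season"][1]).date() if "season" in expo_cfg else None,
        map_cap=float(expo_cfg.get("map_cap", 20.0)),
        snapshot_interval=int(expo_cfg.get("snapshot_interval", 7)),
    )

    dates = [pd.Timestamp(d).date() for d in cfg["synthesis"]["dates"]]
    scenario = ScenarioConfig(
        sites=sites,
        dates=dates,
        depth_range=tuple(cfg["synthesis"].get("depth_range", (800, 1200))),
        euk_rate=float(cfg["synthesis"].get("euk_rate", 0.05)),
        seed=child["synthesis"],
    )
    samples = scenario.samples()

    if external:
        ext = Path(external)
        table = read_biom_json(ext) if ext.suffix == ".biom" or ext.suffix == ".json" else read_otu_tsv(ext)
        meta = pd.read_csv(cfg["synthesis"]["metadata"], sep="\t", index_col=0)
        truth = None
        manifest.status["simulate"] = manifest.status["exposure"] = manifest.status["synthesis"] = "skipped"
    else:
        try:
            grid, flow, sources, tparams, window = _build_scenario(cfg)
            tracers = run_simulation(grid, flow, sources, tparams, window)
            tracers.to_netcdf(outdir / "tracers.nc")
            done("simulate", tracers=outdir / "tracers.nc")
        except Exception:
            manifest.status["simulate"] = "failed"
            manifest.to_json(outdir / "manifest.json")
            raise

        result = exposure_map(tracers, params)
        import xarray as xr

        x, y = grid.cell_centers
        xr.Dataset(
            {
                "index": (("tracer", "y", "x"), result.index),
                "combined": (("y", "x"), result.combined),
                "capped": (("y", "x"), result.capped_map),
            },
            coords={"tracer": result.tracer_names, "y": y, "x": x},
        ).to_netcdf(outdir / "exposure.nc", engine="scipy")
        write_tsv(site_exposure_table(tracers, sites, params), outdir / "site_exposure.tsv", index=False)
        done("exposure", maps=outdir / "exposure.nc", sites=outdir / "site_exposure.tsv")

        # per-sample driver: exposure accumulated over the preceding weeks,
        # as the difference of running cumulatives over the whole run
        recent = int(expo_cfg.get("recent_window_days", 28))
        expo = {}
        for site in sites:
            for d in dates:
                sid = f"{site.id}_{d.isoformat()}"
                end = pd.Timestamp(d)
                start = end - pd.Timedelta(days=recent)
                both = exposure_at_dates(
                    tracers, site.cell, [start, end],
                    ExposureParams(threshold_fraction=params.threshold_fraction, map_cap=params.map_cap),
                )
                expo[sid] = float(both.iloc[1] - both.iloc[0])
        expo = pd.Series(expo)

        table, truth = generate_otu_table(scenario, expo)
        write_biom_json(table, outdir / "otu_table.biom.json")
        write_otu_tsv(table, outdir / "otu_table.tsv")
        write_tsv(truth, outdir / "truth.tsv")
        meta = samples.copy()
        done("synthesis", biom=outdir / "otu_table.biom.json", tsv=outdir / "otu_table.tsv",
             truth=outdir / "truth.tsv")

    env = generate_environment(scenario)
    env_data = env.data.copy()
    env_data["water_qual_idx"] = water_quality_index(env_data)
    write_tsv(env_data, outdir / "environment.tsv")
    write_tsv(env.factors, outdir / "environment_factors_truth.tsv")
    done("environment", table=outdir / "environment.tsv")

    # --- diversity ---------------------------------------------------------
    depth = int(cfg["analysis"].get("rarefaction_depth", 279))
    prok = table.prokaryotes()
    epr = eukaryote_prokaryote_ratio(table)
    rare, dropped = rarefy(prok, depth, mode="draw", seed=child["rarefaction"])
    alpha = alpha_diversity_table(rare)
    alpha = alpha.join(meta).join(epr.rename("epr"))
    write_tsv(alpha, outdir / "diversity.tsv")
    comparisons = {}
    if {"season", "category"} <= set(meta.columns):
        sub = alpha[alpha["category"] == "plume"]
        for metric in ("richness", "shannon", "evenness"):
            dry = sub.loc[sub["season"] == "dry", metric]
            wet = sub.loc[sub["season"] == "wet", metric]
            if len(dry) and len(wet):
                comparisons[f"plume_{metric}_dry_gt_wet"] = mann_whitney_one_sided(dry, wet, "greater")
    (outdir / "diversity_tests.json").write_text(json.dumps(comparisons, indent=2))
    done("diversity", table=outdir / "diversity.tsv", tests=outdir / "diversity_tests.json",
         dropped=dropped)

    # --- multivariate ------------------------------------------------------
    n_perm = int(cfg["analysis"].get("n_perm", 999))
    rel = rare.relative_abundance()
    H, D = hellinger_and_distance(rel)
    ord_res = pcoa(D)
    write_tsv(ord_res.samples.join(meta.reindex(ord_res.samples.index)), outdir / "pcoa_scores.tsv")

    terms = list(cfg["analysis"].get("permanova_terms", ["category", "season"]))
    meta_rare = meta.reindex(rel.index)
    perm = permanova(D, meta_rare, terms, n_perm=n_perm, seed=child["permanova"])
    write_tsv(perm, outdir / "permanova.tsv")

    ind = indval(rel, meta_rare["category"], n_perm=n_perm, seed=child["indval"])
    write_tsv(ind.table, outdir / "indval.tsv")

    env_rare = env_data.reindex(rel.index)
    candidates = [c for c in cfg["analysis"].get("rda_candidates", []) if c in env_rare.columns]
    rda_out = {}
    if candidates:
        selected = stepwise_aic_rda(H, env_rare[candidates])
        rda_terms = selected["terms"] or candidates
        fit = rda(H, env_rare[rda_terms], n_perm=n_perm, seed=child["rda"])
        write_tsv(fit.samples, outdir / "rda_sample_scores.tsv")
        rda_out = {
            "selected_terms": selected["terms"],
            "aic": selected["aic"],
            "constrained_proportion": fit.extras["constrained_proportion"],
            "p": fit.p_value,
        }

    efa_vars = [c for c in env_data.columns if c not in ("bottom_depth", "water_qual_idx")]
    fm = efa(env_data[efa_vars], n_factors="auto", seed=child["efa"])
    write_tsv(fm.loadings, outdir / "efa_loadings.tsv")
    screen = pearson_matrix(env_data[efa_vars])

    est_w = None
    if truth is not None:
        est = estimate_riverine_fraction(table, riverine_endmember().taxa.index)
        joined = truth.join(est.rename("w_estimated"))
        write_tsv(joined[["w_riverine", "w_estimated", "exposure", "category", "season"]],
                  outdir / "mixing_fraction.tsv")
        est_w = float(joined["w_riverine"].corr(joined["w_estimated"]))

    summary = {
        "permanova": {t: {"R2": float(perm.loc[t, "R2"]), "p": float(perm.loc[t, "p"])} for t in terms},
        "n_indicator_otus": int((ind.table["p"] <= 0.05).sum()),
        "rda": rda_out,
        "efa_factors": int(fm.n_factors),
        "pearson_fraction_r_above_0.3": screen["fraction_above_threshold"],
        "mixing_fraction_truth_correlation": est_w,
        "dropped_samples": dropped,
        "n_perm": n_perm,
        "seed": seed,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    done("multivariate", permanova=outdir / "permanova.tsv", indval=outdir / "indval.tsv",
         summary=outdir / "summary.json")

    manifest.to_json(outdir / "manifest.json")
    return manifest
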