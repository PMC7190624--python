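"""End-to-end orchestration: ingest -> filter -> segment -> lag models ->
step-selection strata and fits (per step scale) -> AIC comparison -> UHC.

The same pipeline runs on user-supplied Movebank-style tracks plus daily
rasters, or on the built-in synthetic demo scenario (three "species" =
AHEAD / ON_FRONT / BEHIND melt-front coupling).  Every stage logs how
many records enter, survive and drop, and the fitted models are written
as JSON plus flat CSV summary tables shaped like the usual
coefficient/SE/z/p/delta-AIC layout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import enviro, models, segmentation, simulate, ssf, tracks, uhc

log = logging.getLogger(__name__)

RASTER_VARS = ("snow", "temperature", "ndvi", "wind_u", "wind_v")
LAG_RESPONSES = ("snow", "temperature", "ndvi", "day_length")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; defaults follow the study design
    (K = 10 alternatives, lags -10..+10 days, step scales 1/3/5 days,
    Argos class >= 2)."""

    tracks_path: str = ""
    rasters_dir: str = ""
    output_dir: str = "snowtrack_out"
    species: str = "species"
    step_scales: list = field(default_factory=lambda: [1, 3, 5])
    K: int = 10
    lag_min: int = -10
    lag_max: int = 10
    min_argos_class: str = "2"
    run_segmentation: bool = True
    fpt_radius_km: float = 100.0
    fpt_threshold_days: float | None = None
    spring_window: tuple = (3, 6)
    resample_tolerance_frac: float = 0.1
    uhc_resamples: int = 1000
    uhc_test_frac: float = 0.3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.spring_window, list):
            cfg.spring_window = tuple(cfg.spring_window)
        return cfg

    def to_yaml(self, path):
        d = asdict(self)
        d["spring_window"] = list(self.spring_window)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def load_rasters(rasters_dir) -> dict:
    rasters_dir = Path(rasters_dir)
    out = {}
    for var in RASTER_VARS:
        p = rasters_dir / f"{var}.nc"
        if p.exists():
            out[var] = enviro.EnvRasterSeries.from_netcdf(p, name=var)
    if "snow" not in out:
        raise FileNotFoundError(f"no snow.nc raster in {rasters_dir}")
    return out


def write_movebank_csv(trackset: tracks.TrackSet, path):
    rows = []
    for tr in trackset:
        f = tr.fixes
        rows.append(pd.DataFrame({
            "individual-local-identifier": f["individual"],
            "timestamp": f["timestamp"].dt.strftime("%Y-%m-%d %H:%M:%S"),
            "location-long": f["lon"], "location-lat": f["lat"],
            "sensor-type": f["sensor"], "argos-lc": f["argos_class"],
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def _fit_table(fits_rows) -> pd.DataFrame:
    """Flat Est/SE/z/p/delta-AIC/weight/LL table across fitted terms."""
    return pd.DataFrame(fits_rows, columns=["species", "response", "predictor", "est",
                                            "se", "z", "p", "delta_aic", "aic_weight",
                                            "loglik", "different"])


def _wald_p(est, se):
    if not np.isfinite(se) or se <= 0:
        return np.nan
    return float(2.0 * sps.norm.sf(abs(est / se)))


def chosen_points(bursts) -> pd.DataFrame:
    """Chosen (observed) fix locations of a burst set as a point table."""
    rows = []
    for b in bursts:
        f = b.fixes
        rows.append(pd.DataFrame({
            "individual": b.individual, "year": b.year,
            "lon": f["lon"], "lat": f["lat"],
            "date": f["timestamp"].dt.tz_localize(None).dt.normalize(),
        }))
    if not rows:
        return pd.DataFrame(columns=["individual", "year", "lon", "lat", "date"])
    return pd.concat(rows, ignore_index=True)


def run_pipeline(config: PipelineConfig, trackset=None, rasters=None) -> dict:
    """Execute the full analysis for one species dataset.

    ``trackset``/``rasters`` may be passed in-memory (the demo does);
    otherwise they are read from ``config.tracks_path`` and
    ``config.rasters_dir``.  Writes CSV/JSON outputs under
    ``config.output_dir`` and returns a report dict with per-stage
    record counts and the fitted models.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = {}
    report = {"species": config.species, "counts": counts}

    try:
        if rasters is None:
            rasters = load_rasters(config.rasters_dir)
        if trackset is None:
            trackset = tracks.read_tracks(config.tracks_path)
        counts["tracks_in"] = len(trackset)
        counts["fixes_in"] = trackset.n_fixes()

        trackset = tracks.filter_quality(trackset, config.min_argos_class)
        counts["tracks_after_quality"] = len(trackset)
        counts["fixes_after_quality"] = trackset.n_fixes()

        if config.run_segmentation:
            segments = []
            for tr in trackset:
                prof = segmentation.first_passage_time(tr, config.fpt_radius_km)
                seg, _, _ = segmentation.extract_migration(
                    tr, prof, config.fpt_threshold_days, config.spring_window)
                if seg is not None and len(seg) >= 3:
                    segments.append(seg)
            spring = tracks.TrackSet(segments)
            seg_rows = [{"individual": s.individual, "year": s.year,
                         "start": s.fixes["timestamp"].iloc[0],
                         "end": s.fixes["timestamp"].iloc[-1], "n_fixes": len(s)}
                        for s in segments]
            pd.DataFrame(seg_rows).to_csv(out_dir / "spring_segments.csv", index=False)
        else:
            spring = trackset
        counts["spring_tracks"] = len(spring)
        counts["spring_fixes"] = spring.n_fixes()

        # ---- lag analysis on one-day chosen locations -----------------
        stage = "lag analysis"
        day_bursts = [b for tr in spring
                      for b in tracks.resample_steps(tr, 1, config.resample_tolerance_frac * 1)]
        points = chosen_points(day_bursts)
        counts["lag_points"] = len(points)
        lag_series = {k: rasters[k] for k in ("snow", "temperature", "ndvi") if k in rasters}
        lags = range(config.lag_min, config.lag_max + 1)
        lag_table = enviro.lag_extract(points, lag_series, lags=lags)
        lag_table.to_csv(out_dir / "lag_table.csv", index=False)

        lag_fits = {}
        lag_rows = []
        for var in LAG_RESPONSES:
            if var != "day_length" and var not in lag_series:
                continue
            try:
                full = models.fit_lag_model(lag_table, var)
                null = models.fit_lag_model(lag_table, var, include_slope=False)
                comp = models.compare_models([full, null])
            except ValueError as e:
                log.warning("lag model for %s skipped: %s", var, e)
                continue
            lag_fits[var] = {"full": full, "null": null, "comparison": comp}
            row_full = comp.table.set_index("name")
            delta_null = float(row_full.loc[null.name, "delta_aic"])
            for term in ("Intercept", "lag"):
                lag_rows.append({
                    "species": config.species, "response": var, "predictor": term,
                    "est": full.params[term], "se": full.se[term],
                    "z": full.params[term] / full.se[term] if full.se[term] else np.nan,
                    "p": _wald_p(full.params[term], full.se[term]),
                    "delta_aic": delta_null, "aic_weight": float(row_full.loc[full.name, "weight"]),
                    "loglik": full.loglik, "different": delta_null > 2.0})
        _fit_table(lag_rows).to_csv(out_dir / "lag_models.csv", index=False)
        report["lag_fits"] = lag_fits

        # ---- step-selection analysis per scale ------------------------
        stage = "step selection"
        ssf_fits = {}
        ssf_rows = []
        strata_by_scale = {}
        for scale in config.step_scales:
            bursts = [b for tr in spring
                      for b in tracks.resample_steps(tr, scale,
                                                     config.resample_tolerance_frac * scale)]
            include_wind = (scale == 1)  # wind enters only at the one-day scale
            strata = ssf.build_strata(bursts, rasters, K=config.K,
                                      seed=config.seed + scale, include_wind=include_wind)
            strata_by_scale[scale] = strata
            counts[f"strata_{scale}d"] = int(strata["stratum"].nunique()) if len(strata) else 0
            strata.to_csv(out_dir / f"strata_{scale}d.csv", index=False)
            if counts[f"strata_{scale}d"] < 10:
                log.warning("%s: too few strata at %dd scale; fits skipped", stage, scale)
                continue
            predictors = [p for p in ("snow", "wind_support", "crosswind") if p in strata.columns]
            screen = models.screen_collinearity(strata, predictors)
            screen.to_csv(out_dir / f"collinearity_{scale}d.csv", index=False)
            predictors = [p for p in predictors
                          if not screen[(screen["flagged"])
                                        & ((screen["var_a"] == p) | (screen["var_b"] == p))
                                        & (screen["reason"] == "correlated")].shape[0]]
            try:
                full = models.fit_conditional_logit(strata, predictors, cluster_robust=True,
                                                    name=f"ssf_{scale}d_full")
                candidates = [full]
                for drop in full.predictors:
                    reduced = models.fit_conditional_logit(
                        strata, [p for p in full.predictors if p != drop],
                        cluster_robust=True, name=f"ssf_{scale}d_drop_{drop}")
                    candidates.append(reduced)
            except models.SeparationError as e:
                log.warning("%s at %dd scale skipped: %s", stage, scale, e)
                continue
            comp = models.compare_models(candidates)
            ssf_fits[scale] = {"full": full, "comparison": comp}
            ctab = comp.table.set_index("name")
            for term in full.predictors:
                dname = f"ssf_{scale}d_drop_{term}"
                d_aic = float(ctab.loc[dname, "aic"] - full.aic)
                ssf_rows.append({
                    "species": config.species, "response": f"choice_{scale}d", "predictor": term,
                    "est": full.params[term], "se": full.se[term],
                    "z": full.params[term] / full.se[term],
                    "p": _wald_p(full.params[term], full.se[term]),
                    "delta_aic": d_aic,
                    "aic_weight": float(ctab.loc[f"ssf_{scale}d_full", "weight"]),
                    "loglik": full.loglik, "different": d_aic > 2.0})
        _fit_table(ssf_rows).to_csv(out_dir / "ssf_models.csv", index=False)
        report["ssf_fits"] = ssf_fits

        # ---- UHC validation at the one-day scale ----------------------
        stage = "UHC validation"
        uhc_results = {}
        strata1 = strata_by_scale.get(1)
        if strata1 is not None and strata1["individual"].nunique() >= 3 and 1 in ssf_fits:
            train, test = uhc.train_test_split_strata(strata1, config.uhc_test_frac,
                                                      seed=config.seed)
            predictors = ssf_fits[1]["full"].predictors
            if train["stratum"].nunique() >= 10 and test["stratum"].nunique() >= 5:
                fit_train = models.fit_conditional_logit(train, predictors, name="uhc_train")
                uhc_results = uhc.uhc_validate(fit_train, test,
                                               n_resamples=config.uhc_resamples,
                                               seed=config.seed)
                for name, r in uhc_results.items():
                    r.to_frame().to_csv(out_dir / f"uhc_{name}.csv", index=False)
        report["uhc"] = uhc_results

        fits_json = {}
        for var, d in lag_fits.items():
            fits_json[f"lag_{var}"] = d["full"].to_dict()
        for scale, d in ssf_fits.items():
            fits_json[f"ssf_{scale}d"] = d["full"].to_dict()
        with open(out_dir / "fits.json", "w") as fh:
            json.dump(fits_json, fh, indent=2, default=str)
        with open(out_dir / "counts.json", "w") as fh:
            json.dump(counts, fh, indent=2)
    except Exception as e:
        raise RuntimeError(f"pipeline failed in stage '{stage if 'stage' in dir() else 'setup'}'"
                           f" for {config.species}: {e}") from e
    return report


# ---------------------------------------------------------------------
# demo scenario
# ---------------------------------------------------------------------

DEMO_BETA = {"snow": -1.0, "wind_support": 0.05, "crosswind": 0.0}


def make_demo(out_dir, n_individuals: int = 20, n_steps: int = 40, seed: int = 0,
              front_config: simulate.SnowFrontConfig | None = None,
              beta: dict | None = None) -> dict:
    """Write the three-mode synthetic demo scenario to disk.

    Three "species" (AHEAD / ON_FRONT / BEHIND coupling, ~20 individuals
    each) move over one shared snowmelt landscape; rasters go to NetCDF,
    tracks to Movebank-style CSV, and the ground-truth strata and
    coefficients to CSV + JSON sidecars.
    """
    out_dir = Path(out_dir)
    (out_dir / "rasters").mkdir(parents=True, exist_ok=True)
    # a little Bernoulli flicker mimics the patchiness of real binary
    # snow products and keeps within-stratum snow variation everywhere
    fc = front_config or simulate.SnowFrontConfig(seed=seed, noise_prob=0.02)
    beta = dict(DEMO_BETA if beta is None else beta)
    snow = simulate.make_snow_series(fc)
    fields = simulate.make_env_fields(fc)
    rasters = {"snow": snow, **fields}
    for name, series in rasters.items():
        series.to_netcdf(out_dir / "rasters" / f"{name}.nc")

    info = {"beta": beta, "seed": seed, "modes": {}, "front_config": asdict(fc)}
    results = {}
    for i, mode in enumerate(simulate.COUPLING_MODES):
        cfg = simulate.AgentConfig(n_individuals=n_individuals, n_steps=n_steps,
                                   coupling=mode, beta=beta, seed=seed + 100 * (i + 1))
        sim = simulate.simulate_agents(cfg, rasters, fc)
        write_movebank_csv(sim.trackset, out_dir / f"tracks_{mode}.csv")
        sim.strata.to_csv(out_dir / f"truth_strata_{mode}.csv", index=False)
        info["modes"][mode] = {"n_tracks": len(sim.trackset),
                               "n_fixes": sim.trackset.n_fixes(),
                               "n_strata": int(sim.strata["stratum"].nunique())}
        log.info("demo %s: %d tracks, %d fixes", mode, len(sim.trackset),
                 sim.trackset.n_fixes())
        results[mode] = sim
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(info, fh, indent=2)
    return {"dir": out_dir, "rasters": rasters, "front_config": fc,
            "simulations": results, "info": info}


def run_demo(out_dir, n_individuals: int = 20, n_steps: int = 40, seed: int = 0,
             uhc_resamples: int = 300) -> dict:
    """make_demo + run_pipeline per mode; returns {mode: report}."""
    demo = make_demo(out_dir, n_individuals=n_individuals, n_steps=n_steps, seed=seed)
    reports = {}
    for mode in simulate.COUPLING_MODES:
        cfg = PipelineConfig(
            tracks_path=str(Path(out_dir) / f"tracks_{mode}.csv"),
            rasters_dir=str(Path(out_dir) / "rasters"),
            output_dir=str(Path(out_dir) / f"analysis_{mode}"),
            species=mode, seed=seed, uhc_resamples=uhc_resamples,
            run_segmentation=False,  # demo tracks are pure spring migration
        )
        reports[mode] = run_pipeline(cfg, rasters=demo["rasters"])
    return {"demo": demo, "reports": reports}
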