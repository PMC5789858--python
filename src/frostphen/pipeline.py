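"""End-to-end orchestration of the frost-phenology analysis.

A :class:`RunConfig` (constructed directly or loaded from YAML) names
either a synthetic world to generate or NetCDF/CSV inputs to load, the
decade definitions, and the stage parameters.  :func:`run` executes
synthetic generation -> phenology extraction -> frost counting -> decadal
change -> attribution -> spatial association (-> in-situ comparison when a
site table is present), writes every declared artifact under the output
directory and records a manifest with the config, seeds and versions.
The numbered scripts under ``analysis/`` drive the same stages
individually.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import association, attribution, change, frost, grid_io
from . import insitu as insitu_mod
from . import phenology as phen_mod
from . import synthetic

_VERSION = "0.1.0"

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    out_dir: str = "results/run"
    seed: int = 0
    years: tuple[int, int] = (1982, 2012)
    # synthetic world (used when ndvi_path/tmin_path are absent)
    n_lat: int = 16
    n_lon: int = 32
    truth_ranges: dict = field(default_factory=dict)
    ndvi_noise_sd: float = 0.02
    timestep_hours: int = 3
    n_sites: int = 0
    # real inputs
    ndvi_path: str | None = None
    tmin_path: str | None = None
    site_table_path: str | None = None
    # stage parameters
    methods: tuple[str, ...] = phen_mod.METHODS
    cutoff_mode: str = "solstice"
    decade_a: tuple[int, int] = (1982, 1989)
    decade_b: tuple[int, int] = (2000, 2009)
    n_draws: int = 10
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        for p in (self.ndvi_path, self.tmin_path, self.site_table_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input {p} does not exist")

    @property
    def year_array(self) -> np.ndarray:
        return np.arange(self.years[0], self.years[1] + 1)

    def decade(self, which: str) -> range:
        a, b = self.decade_a if which == "a" else self.decade_b
        return range(a, b + 1)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the in-memory artifact bundle."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    stage = "setup"
    try:
        bundle = _run_stages(cfg, out)
    except Exception as exc:
        stage = getattr(exc, "_stage", stage)
        failed_marker.write_text(f"stage={stage}: {exc}\n")
        raise
    manifest = {
        "config": asdict(cfg),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "version": _VERSION,
        "artifacts": sorted(p.name for p in out.iterdir()
                            if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    bundle["manifest"] = manifest
    return bundle


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            logger.info("stage %s", name)
            try:
                return fn(*a, **k)
            except Exception as exc:
                exc._stage = name
                raise
        return wrapped
    return deco


def _run_stages(cfg: RunConfig, out: Path) -> dict:
    years = cfg.year_array
    bundle: dict = {}

    @_stage("inputs")
    def load_inputs():
        if cfg.ndvi_path and cfg.tmin_path:
            ndvi = grid_io.read_ndvi(cfg.ndvi_path)
            tmin = grid_io.read_tmin(cfg.tmin_path)
        else:
            truth = synthetic.gen_truth(cfg.n_lat, cfg.n_lon,
                                        cfg.truth_ranges or None,
                                        seed=cfg.seed)
            ndvi = synthetic.gen_ndvi(truth, years, cfg.ndvi_noise_sd,
                                      seed=cfg.seed + 1)
            tmin = synthetic.gen_tmin(truth, years, cfg.timestep_hours,
                                      seed=cfg.seed + 2)
            grid_io.write_ndvi(ndvi, out / "ndvi.nc")
            grid_io.write_tmin(tmin, out / "tmin.nc")
        return ndvi, tmin

    ndvi, tmin = load_inputs()
    bundle["ndvi"], bundle["tmin"] = ndvi, tmin

    @_stage("phenology")
    def do_phenology():
        grids = phen_mod.extract_phenology(ndvi, methods=cfg.methods)
        for name, g in grids.items():
            grid_io.write_phenology(g, out / f"phenology_{name}.nc")
        return grids

    phen = do_phenology()
    bundle["phenology"] = phen
    ens = phen["ensemble"]

    @_stage("frost")
    def do_frost():
        daily = frost.daily_min(tmin)
        counts = frost.count_grid(daily, ens, cfg.cutoff_mode)
        return daily, counts

    daily, counts = do_frost()
    bundle["daily_tmin"], bundle["counts"] = daily, counts

    @_stage("decadal_change")
    def do_change():
        dec_a, dec_b = cfg.decade("a"), cfg.decade("b")
        maps = {}
        for name, metric in (("gsfd", counts.gsfd), ("spr_fd", counts.spr_fd),
                             ("fal_fd", counts.fal_fd), ("sos", ens.sos),
                             ("eos", ens.eos), ("gsl", ens.gsl)):
            maps[name] = change.difference_test(
                metric, years, dec_a, dec_b, ens.lat_axis, ens.lon_axis,
                alpha=cfg.alpha)
        return maps

    change_maps = do_change()
    bundle["change"] = change_maps

    @_stage("attribution")
    def do_attribution():
        fix_phen = attribution.run_scenario(
            daily, ens, "fix_phenology", cfg.n_draws, seed=cfg.seed + 3,
            cutoff_mode=cfg.cutoff_mode)
        fix_temp = attribution.run_scenario(
            daily, ens, "fix_temperature", cfg.n_draws, seed=cfg.seed + 4,
            cutoff_mode=cfg.cutoff_mode)
        dec_a, dec_b = cfg.decade("a"), cfg.decade("b")
        cm_temp = change.difference_test(fix_phen.draw_mean, years, dec_a,
                                         dec_b, ens.lat_axis, ens.lon_axis,
                                         alpha=cfg.alpha)
        cm_phen = change.difference_test(fix_temp.draw_mean, years, dec_a,
                                         dec_b, ens.lat_axis, ens.lon_axis,
                                         alpha=cfg.alpha)
        codes, _, _ = attribution.attribute_change(
            change_maps["gsfd"], cm_temp, cm_phen)
        draws = {"fix_phenology": fix_phen.draw_years.tolist(),
                 "fix_temperature": fix_temp.draw_years.tolist(),
                 "seeds": {"fix_phenology": cfg.seed + 3,
                           "fix_temperature": cfg.seed + 4}}
        (out / "draws.json").write_text(json.dumps(draws, indent=2))
        return {"fix_phenology": fix_phen, "fix_temperature": fix_temp,
                "delta_temp_only": cm_temp, "delta_phen_only": cm_phen,
                "dominance": codes}

    bundle["attribution"] = do_attribution()

    @_stage("association")
    def do_association():
        dec_a, dec_b = cfg.decade("a"), cfg.decade("b")
        # growing-season mean T_min change as the temperature covariate
        gs_tmin = _growing_season_mean_tmin(daily, ens)
        d_tmin = change.difference_test(gs_tmin, years, dec_a, dec_b,
                                        ens.lat_axis, ens.lon_axis).delta
        pcm = association.moving_window_partial(
            change_maps["gsfd"].delta, change_maps["gsl"].delta, d_tmin,
            ens.lat_axis, ens.lon_axis)
        pe, fe, density, quad = association.binned_change_density(
            change_maps["gsl"].delta, change_maps["gsfd"].delta)
        try:
            slope = association.continental_association(
                change_maps["gsl"].delta, change_maps["gsfd"].delta,
                ens.lat_axis)
        except ValueError:          # grid too small for a stable slope
            slope = None
        np.savetxt(out / "change_density.csv", density, delimiter=",")
        return {"partial": pcm, "density": (pe, fe, density, quad),
                "slope": slope, "delta_tmin": d_tmin}

    bundle["association"] = do_association()

    if cfg.site_table_path or cfg.n_sites > 0:
        @_stage("insitu")
        def do_insitu():
            if cfg.site_table_path:
                table = grid_io.read_site_table(cfg.site_table_path)
            else:
                table = synthetic.gen_insitu(ndvi.truth, cfg.n_sites, years,
                                             seed=cfg.seed + 5)
                grid_io.write_site_table(table, out / "sites.csv")
            clean, sets = insitu_mod.filter_sites(
                table, start_year=int(years[0]),
                end_year=int(min(years[-1], 2009)), min_years=min(
                    28, years.size - 3))
            site_counts = insitu_mod.site_frost_counts(clean, daily)
            return {"table": clean, "sets": sets, "counts": site_counts}

        bundle["insitu"] = do_insitu()

    return bundle


def _growing_season_mean_tmin(daily, phen) -> np.ndarray:
    """Mean daily T_min inside each pixel's climatological season window."""
    ny = daily.values.shape[0]
    with np.errstate(invalid="ignore"):
        sos = np.nanmean(phen.sos, axis=0)
        eos = np.nanmean(phen.eos, axis=0)
    nlat, nlon = sos.shape
    outv = np.full((ny, nlat, nlon), np.nan)
    doy = np.arange(1, 366)
    for iy in range(nlat):
        for ix in range(nlon):
            if not (np.isfinite(sos[iy, ix]) and np.isfinite(eos[iy, ix])):
                continue
            sel = (doy >= sos[iy, ix]) & (doy <= eos[iy, ix])
            outv[:, iy, ix] = daily.values[:, sel, iy, ix].mean(axis=1)
    return outv
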