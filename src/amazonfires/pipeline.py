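"""Config-driven orchestration of the full fire-decoupling analysis.

Stages chain through plain files in the output directory (CSV tables,
NetCDF rasters, a JSON manifest with content hashes), so any stage can be
re-run from cached intermediates and external tools can verify every
product.  In ``synthetic`` mode the inputs come from
:mod:`amazonfires.synthetic`; in ``files`` mode the user supplies a
detection table, a landscape raster, a deforestation table and a [CO]
table in the same formats.

The eight analysis products: annual total/type counts, fires-per-km²
ratio series, phase regressions, anomaly-extent series, [CO] analyses
(trend, regression on deforestation, window adjustment, sensitivity scan),
FRP percentiles + densities, the FRP90 breakpoint report, and the per-type
mode decompositions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anomalies, classify, emissions, intensity, modes, trends
from .io import (GridSpec, annual_deforestation_km2, load_raster, read_detections,
                 rasterize_counts, save_raster, write_detections)
from .synthetic import (SyntheticConfig, generate_co_series, generate_fire_seasons,
                        generate_landscape, generate_monthly_co)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "classify", "trends", "anomalies", "frp", "modes", "co")

_FLOAT_FMT = "%.10g"


class ConfigError(ValueError):
    """Invalid pipeline configuration (names the offending field)."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


@dataclass
class PipelineConfig:
    mode: str = "synthetic"                  # 'synthetic' | 'files'
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    # files mode inputs
    detections_path: str | None = None
    landscape_path: str | None = None
    defor_km2_path: str | None = None
    co_path: str | None = None
    co_monthly_path: str | None = None
    # analysis parameters
    thresholds: classify.ClassificationThresholds = field(
        default_factory=classify.ClassificationThresholds)
    phases: tuple = trends.DEFAULT_PHASES
    anomaly_threshold: float = 2.0
    frp_percentile_level: float = 90.0
    breakpoint_range: tuple[int, int] = (2005, 2017)
    alpha_fire_trend: float = 0.01
    alpha_other: float = 0.05
    sensitivity_target_years: tuple[int, ...] = (2007, 2010)
    sensitivity_step_pct: float = 5.0
    window_adjust_year: int | None = 2015    # Apr–Mar window for this year
    outdir: str = "pipeline_out"
    seed: int | None = None                  # overrides synthetic.seed when set

    def __post_init__(self):
        if self.mode not in ("synthetic", "files"):
            raise ConfigError(f"mode must be 'synthetic' or 'files', got {self.mode!r}")
        if self.mode == "files":
            for name in ("detections_path", "landscape_path", "defor_km2_path", "co_path"):
                p = getattr(self, name)
                if p is None:
                    raise ConfigError(f"files mode requires {name}")
                if not Path(p).exists():
                    raise ConfigError(f"{name}: no such file: {p}")
        if self.seed is not None and self.mode == "synthetic":
            self.synthetic = dataclasses.replace(self.synthetic, seed=int(self.seed))

    @property
    def grid_spec(self) -> GridSpec:
        return self.synthetic.grid_spec

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(self.synthetic.years)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phases"] = [dataclasses.asdict(p) for p in self.phases]
        return d


def validate_config(path) -> PipelineConfig:
    """Load a YAML pipeline config, inject defaults, and validate.

    An empty file yields the full default configuration.  Field errors raise
    :class:`ConfigError` naming the field.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    raw = dict(raw)
    try:
        if "synthetic" in raw and isinstance(raw["synthetic"], dict):
            syn = dict(raw["synthetic"])
            for k in ("years", "type_mix", "drought_years", "tree_cover_mix",
                      "season_months", "frp_breakpoint"):
                if k in syn and syn[k] is not None:
                    syn[k] = tuple(syn[k])
            if "frp_params_by_type" in syn:
                syn["frp_params_by_type"] = {k: tuple(v)
                                             for k, v in syn["frp_params_by_type"].items()}
            raw["synthetic"] = SyntheticConfig(**syn)
        if "thresholds" in raw and isinstance(raw["thresholds"], dict):
            raw["thresholds"] = classify.ClassificationThresholds(**raw["thresholds"])
        if "phases" in raw:
            raw["phases"] = tuple(trends.PhaseDefinition(**p) if isinstance(p, dict) else p
                                  for p in raw["phases"])
        for k in ("breakpoint_range", "sensitivity_target_years"):
            if k in raw and raw[k] is not None:
                raw[k] = tuple(raw[k])
        return PipelineConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def echo_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index=True) -> None:
    df.to_csv(path, float_format=_FLOAT_FMT, index=index)


def _reg_row(name: str, r: trends.RegressionResult) -> dict:
    return {"series": name, "slope": r.slope, "intercept": r.intercept,
            "r_squared": r.r_squared, "p_value": r.p_value, "n": r.n,
            "low_n": r.low_n, "testable": r.testable}


class Pipeline:
    """Stage runner bound to one configuration and output directory."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.products: list[str] = []

    # ---- intermediate access -------------------------------------------------
    def _path(self, name: str) -> Path:
        return self.outdir / name

    def _detections(self) -> pd.DataFrame:
        p = self._path("detections.csv")
        if not p.exists():
            if self.config.mode == "files":
                p = Path(self.config.detections_path)
            else:
                self.stage_simulate()
        return read_detections(p, self.config.grid_spec, study_years=self.config.years)

    def _landscape(self):
        p = self._path("landscape.nc")
        if not p.exists():
            if self.config.mode == "files":
                p = Path(self.config.landscape_path)
            else:
                self.stage_simulate()
        return load_raster(p)

    def _defor_km2(self) -> pd.Series:
        p = self._path("deforestation_km2.csv")
        if not p.exists() and self.config.mode == "files":
            p = Path(self.config.defor_km2_path)
        if not p.exists():
            self.stage_simulate()
            p = self._path("deforestation_km2.csv")
        df = pd.read_csv(p)
        return pd.Series(df["defor_km2"].to_numpy(), index=df["year"].astype(int))

    def _co(self) -> pd.Series:
        p = self._path("co_series.csv")
        if not p.exists() and self.config.mode == "files":
            p = Path(self.config.co_path)
        if not p.exists():
            self.stage_simulate()
            p = self._path("co_series.csv")
        df = pd.read_csv(p)
        return pd.Series(df["co_ppbv"].to_numpy(), index=df["year"].astype(int))

    def _co_monthly(self) -> pd.Series | None:
        p = self._path("co_monthly.csv")
        if not p.exists() and self.config.mode == "files":
            if self.config.co_monthly_path is None:
                return None
            p = Path(self.config.co_monthly_path)
        if not p.exists():
            return None
        df = pd.read_csv(p)
        return pd.Series(df["co_ppbv"].to_numpy(),
                         index=pd.PeriodIndex(df["month"], freq="M"))

    def _labeled(self) -> pd.DataFrame:
        p = self._path("labeled_detections.csv")
        if not p.exists():
            self.stage_classify()
        df = pd.read_csv(p)
        df["date"] = pd.to_datetime(df["date"])
        return df

    # ---- stages --------------------------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.config
        if cfg.mode != "synthetic":
            raise ConfigError("simulate stage requires synthetic mode")
        syn = cfg.synthetic
        logger.info("simulate: grid %dx%d, years %d-%d, seed %s",
                    syn.grid_rows, syn.grid_cols, syn.years[0], syn.years[-1], syn.seed)
        land = generate_landscape(syn)
        det, truth = generate_fire_seasons(syn, land)
        totals = det.assign(year=pd.to_datetime(det["date"]).dt.year) \
                    .groupby("year").size().reindex(syn.years, fill_value=0)
        co = generate_co_series(syn, totals)
        co_monthly = generate_monthly_co(syn, co)

        save_raster(land, self._path("landscape.nc"))
        write_detections(det, self._path("detections.csv"))
        truth.detection_labels.to_frame().to_csv(self._path("truth_labels.csv"),
                                                 index_label="detection")
        _write_csv(truth.expected_totals.rename("expected_total").to_frame(),
                   self._path("expected_totals.csv"))
        _write_csv(annual_deforestation_km2(land).to_frame(),
                   self._path("deforestation_km2.csv"))
        _write_csv(co.rename("co_ppbv").to_frame(), self._path("co_series.csv"))
        cm = co_monthly.rename("co_ppbv").to_frame()
        cm.index = cm.index.astype(str)
        _write_csv(cm.rename_axis("month"), self._path("co_monthly.csv"))
        syn.to_yaml(self._path("synthetic_config.yaml"))
        self.products += ["landscape.nc", "detections.csv", "truth_labels.csv",
                          "expected_totals.csv", "deforestation_km2.csv",
                          "co_series.csv", "co_monthly.csv", "synthetic_config.yaml"]

    def stage_classify(self) -> None:
        det = self._detections()
        land = self._landscape()
        logger.info("classify: %d detections", len(det))
        labeled = classify.classify_all(det, land, self.config.thresholds)
        counts = classify.annual_type_counts(labeled, years=self.config.years)
        write_detections(labeled, self._path("labeled_detections.csv"))
        _write_csv(counts, self._path("annual_type_counts.csv"))
        self.products += ["labeled_detections.csv", "annual_type_counts.csv"]

    def stage_trends(self) -> None:
        cfg = self.config
        counts = pd.read_csv(self._path_or_make("annual_type_counts.csv",
                                                self.stage_classify), index_col="year")
        fires = counts["total"].astype(float)
        defor = self._defor_km2().reindex(fires.index)

        tr = trends.mann_kendall(fires, alpha=cfg.alpha_fire_trend)
        trend_rows = [{
            "series": "total_fires", "sen_slope": tr.sen_slope,
            "sen_ci_low": tr.sen_ci_low, "sen_ci_high": tr.sen_ci_high,
            "mk_s": tr.mk_s, "mk_z": tr.mk_z, "p_two_tailed": tr.p_two_tailed,
            "alpha": tr.alpha, "significant": tr.significant, "n": tr.n,
        }]
        ratio = trends.fires_per_area_ratio(fires, defor)
        rr = trends.mann_kendall(ratio, alpha=cfg.alpha_other)
        trend_rows.append({
            "series": "fires_per_km2", "sen_slope": rr.sen_slope,
            "sen_ci_low": rr.sen_ci_low, "sen_ci_high": rr.sen_ci_high,
            "mk_s": rr.mk_s, "mk_z": rr.mk_z, "p_two_tailed": rr.p_two_tailed,
            "alpha": rr.alpha, "significant": rr.significant, "n": rr.n,
        })
        ratio_ols = trends.ols_regression(ratio.index.to_numpy(dtype=float),
                                          ratio.to_numpy())
        phase = trends.phase_regressions(fires, defor, cfg.phases)

        _write_csv(pd.DataFrame(trend_rows), self._path("trend_results.csv"), index=False)
        _write_csv(ratio.to_frame(), self._path("ratio_series.csv"))
        rows = [_reg_row("ratio_on_time", ratio_ols)]
        rows += [_reg_row(name, r) for name, r in phase.items()]
        _write_csv(pd.DataFrame(rows), self._path("phase_regressions.csv"), index=False)
        self.products += ["trend_results.csv", "ratio_series.csv", "phase_regressions.csv"]

    def stage_anomalies(self) -> None:
        det = self._detections()
        grids = rasterize_counts(det, self.config.years, self.config.grid_spec)
        z = anomalies.standardize(grids)
        ext_valid = anomalies.extent_above(z, self.config.anomaly_threshold, "valid")
        ext_all = anomalies.extent_above(z, self.config.anomaly_threshold, "all")
        out = pd.DataFrame({"pct_of_fire_affected_area": ext_valid,
                            "pct_of_total_area": ext_all})
        out.index.name = "year"
        _write_csv(out, self._path("anomaly_extent.csv"))
        save_raster(z.to_dataset(name="z"), self._path("anomaly_fields.nc"))
        self.products += ["anomaly_extent.csv", "anomaly_fields.nc"]

    def stage_frp(self) -> None:
        cfg = self.config
        lab = self._labeled()
        lab = lab[np.isfinite(lab["frp_mw"])]
        by_type = {t: g["frp_mw"].to_numpy() for t, g in lab.groupby("fire_type")}
        by_year = {int(y): g["frp_mw"].to_numpy()
                   for y, g in lab.groupby(lab["date"].dt.year)}
        ptab_type = intensity.percentile_table(by_type, cfg.frp_percentile_level)
        ptab_year = intensity.percentile_table(by_year, cfg.frp_percentile_level)
        _write_csv(ptab_type, self._path("frp90_by_type.csv"), index=False)
        _write_csv(ptab_year, self._path("frp90_by_year.csv"), index=False)

        dens = intensity.frp_density(by_type)
        for t, d in dens.items():
            _write_csv(d, self._path(f"frp_density_{t}.csv"), index=False)
            self.products.append(f"frp_density_{t}.csv")

        frp90 = pd.Series({r.group: r.value
                           for r in intensity.frp_percentile(by_year,
                                                             cfg.frp_percentile_level)})
        frp90 = frp90.sort_index()
        fit = intensity.breakpoint_fit(frp90, cfg.breakpoint_range,
                                       alpha=cfg.alpha_other)
        report = {
            "breakpoint_year": fit.breakpoint_year,
            "pre_slope_mw_per_yr": fit.pre_slope,
            "post_slope_mw_per_yr": fit.post_slope,
            "sse": fit.sse,
            "single_line_sse": fit.single_line_sse,
            "no_break": fit.no_break,
            "pre_branch_p": fit.mk_pre.p_two_tailed,
            "pre_branch_significant": fit.mk_pre.significant,
            "post_branch_p": fit.mk_post.p_two_tailed,
            "post_branch_significant": fit.mk_post.significant,
            "sse_by_candidate": {str(k): v for k, v in fit.sse_by_candidate.items()},
        }
        self._path("breakpoint_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
        self.products += ["frp90_by_type.csv", "frp90_by_year.csv",
                          "breakpoint_report.json"]

    def stage_modes(self) -> None:
        lab = self._labeled()
        decomps = {}
        pcs_frames = []
        for t in classify.FIRE_TYPES:
            sub = lab[lab["fire_type"] == t]
            grids = rasterize_counts(sub, self.config.years, self.config.grid_spec)
            z = anomalies.standardize(grids)
            d = modes.decompose(z, fire_type=t)
            decomps[t] = d
            pcs = d.pcs.copy()
            pcs.insert(0, "fire_type", t)
            pcs_frames.append(pcs)
            signs = modes.eof_sign_maps(d, range(min(3, d.eofs.shape[0])))
            save_raster(signs.to_dataset(name="eof_sign"),
                        self._path(f"eof_signs_{t}.nc"))
            self.products.append(f"eof_signs_{t}.nc")
        _write_csv(modes.variance_table(decomps), self._path("mode_variances.csv"),
                   index=False)
        _write_csv(pd.concat(pcs_frames), self._path("pc_series.csv"))
        self.products += ["mode_variances.csv", "pc_series.csv"]

    def stage_co(self) -> None:
        cfg = self.config
        co = self._co()
        defor = self._defor_km2()
        monthly = self._co_monthly()

        rows = [_reg_row("co_on_time", emissions.co_trend(co, cfg.alpha_other)),
                _reg_row("co_on_deforestation",
                         emissions.co_on_deforestation(co, defor, cfg.alpha_other))]
        if monthly is not None and cfg.window_adjust_year in co.index:
            adj = emissions.window_adjust(co, monthly, cfg.window_adjust_year)
            rows.append(_reg_row("co_on_time_window_adjusted",
                                 emissions.co_trend(adj, cfg.alpha_other)))
            rows.append(_reg_row("co_on_deforestation_window_adjusted",
                                 emissions.co_on_deforestation(adj, defor,
                                                               cfg.alpha_other)))
            co_for_scan = adj
        else:
            co_for_scan = co
        sens = emissions.sensitivity_scan(co_for_scan, cfg.sensitivity_target_years,
                                          cfg.sensitivity_step_pct, cfg.alpha_other)
        _write_csv(pd.DataFrame(rows), self._path("co_regressions.csv"), index=False)
        _write_csv(sens.profile, self._path("co_sensitivity_profile.csv"), index=False)
        summary = {
            "target_years": list(sens.target_years),
            "step_pct": sens.step_pct,
            "alpha": sens.alpha,
            "minimal_reduction_pct": sens.minimal_reduction_pct,
            "p_at_minimum": sens.p_at_minimum,
            "r2_at_minimum": sens.r2_at_minimum,
        }
        self._path("co_sensitivity.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True))
        self.products += ["co_regressions.csv", "co_sensitivity_profile.csv",
                          "co_sensitivity.json"]

    def _path_or_make(self, name: str, maker) -> Path:
        p = self._path(name)
        if not p.exists():
            maker()
        return p

    # ---- driver --------------------------------------------------------------
    def run(self, stages=None) -> dict:
        stages = list(stages if stages is not None else STAGES)
        if self.config.mode == "files" and "simulate" in stages:
            stages.remove("simulate")
        done = []
        try:
            for st in stages:
                getattr(self, f"stage_{st}")()
                done.append(st)
        except Exception as exc:  # noqa: BLE001 - manifest must name the stage
            manifest = self._manifest(done, partial=True, failed_stage=st)
            self._write_manifest(manifest)
            raise StageError(st, exc) from exc
        manifest = self._manifest(done, partial=False)
        self._write_manifest(manifest)
        return manifest

    def _manifest(self, stages_done, partial: bool, failed_stage: str | None = None) -> dict:
        files = {}
        for name in sorted(set(self.products)):
            p = self._path(name)
            if p.exists():
                files[name] = {"sha256": _sha256(p), "bytes": p.stat().st_size}
        m = {
            "stages_completed": list(stages_done),
            "partial": partial,
            "config": self.config.to_dict(),
            "files": files,
        }
        if failed_stage:
            m["failed_stage"] = failed_stage
        return m

    def _write_manifest(self, manifest: dict) -> None:
        self._path("manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str))


def run_pipeline(config: PipelineConfig, stages=None) -> dict:
    """Run the configured stages and return the output manifest."""
    return Pipeline(config).run(stages)
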