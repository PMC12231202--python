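"""End-to-end orchestration: raw tables -> covariates -> fates -> inference.

``run_pipeline`` chains the stages on real or synthetic inputs and emits the
analysis artifacts: the per-individual covariate table, fate records,
Kaplan-Meier curves with log-rank tests per design factor, spatial clustering
with Global Moran's I on survival times, and the Cox model-selection table
with the final model. ``simulate_and_validate`` runs the whole chain on a
synthetic cohort and scores it against the generator's ground truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import migration, mortality, space_use, survival, synthetic, telemetry_io
from .activity import ActivityWindowError, activity_average, daily_activity, local_date

log = logging.getLogger(__name__)

#: Candidate covariates entering the Cox screening, as named in the outputs.
COX_CANDIDATES = ("Releasetime", "StayDur", "ActAvg", "KDE", "Weight", "VISIB", "WDSP", "TEMP", "PRCP")

#: Study-design factors compared with Kaplan-Meier / log-rank.
DESIGN_FACTORS = ("species", "release_site", "source", "tracker", "release_year")

#: How generator fates map to classifier fates.
TRUTH_TO_FATE = {
    "survivor_migrant": "censored",
    "censored_resident": "censored",
    "natural_death": "dead_confirmed",
    "hunting_loss": "hunting_or_loss",
}


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


@dataclass
class PipelineConfig:
    fixes_path: str | None = None
    weather_path: str | None = None
    meta_path: str | None = None
    output_dir: str | None = None
    seed: int = 0
    accuracy_keep: tuple = ("A", "B", "C")
    min_hours_per_day: int = 20
    min_displacement_km: float = 50.0
    min_sustain_h: float = 48.0
    thermal_tol_c: float = 2.0
    thermal_dur_h: float = 72.0
    quiescence_max_count: int = 10
    quiescence_dur_h: float = 24.0
    confinement_radius_m: float = 200.0
    confinement_dur_h: float = 72.0
    horizon_days: int = 365
    gap_fill_h: int = 6
    kde_bandwidth: object = "silverman"
    morans_permutations: int = 999
    cluster_linkage: str = "complete"
    cluster_k: int | None = None
    vif_threshold: float = 5.0
    delta_aic: float = 2.0

    def validate(self) -> None:
        positive = (
            "min_displacement_km", "min_sustain_h", "thermal_tol_c", "thermal_dur_h",
            "quiescence_max_count", "quiescence_dur_h", "confinement_radius_m",
            "confinement_dur_h", "horizon_days", "vif_threshold", "delta_aic",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        cfg = cls(**d)
        if isinstance(cfg.accuracy_keep, list):
            cfg.accuracy_keep = tuple(cfg.accuracy_keep)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["accuracy_keep"] = list(self.accuracy_keep)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True, default=str).encode()).hexdigest()[:16]

    def mortality_params(self) -> mortality.MortalityParams:
        return mortality.MortalityParams(
            thermal_tol_c=self.thermal_tol_c,
            thermal_dur_h=self.thermal_dur_h,
            quiescence_max_count=self.quiescence_max_count,
            quiescence_dur_h=self.quiescence_dur_h,
            confinement_radius_m=self.confinement_radius_m,
            confinement_dur_h=self.confinement_dur_h,
            horizon_days=self.horizon_days,
            gap_fill_h=self.gap_fill_h,
        )

    def departure_params(self) -> migration.DepartureParams:
        return migration.DepartureParams(
            min_displacement_km=self.min_displacement_km, min_sustain_h=self.min_sustain_h
        )


@dataclass
class PipelineReport:
    covariates: pd.DataFrame
    fates: pd.DataFrame
    km_curves: pd.DataFrame
    logrank_tests: pd.DataFrame
    clusters: pd.DataFrame
    morans: dict
    model_table: pd.DataFrame
    final_model: dict
    config: PipelineConfig
    fate_records: dict = field(default_factory=dict, repr=False)
    selection: survival.ModelSelection | None = field(default=None, repr=False)


class StageError(RuntimeError):
    def __init__(self, stage: str, individual: str | None, cause: Exception):
        super().__init__(f"stage '{stage}' failed" + (f" for individual {individual}" if individual else "") + f": {cause}")
        self.stage = stage
        self.individual = individual
        self.cause = cause


def _load_inputs(config: PipelineConfig, cohort: synthetic.SimulatedCohort | None):
    if cohort is not None:
        return cohort.fixes.copy(), cohort.weather.copy(), cohort.meta.copy()
    if not (config.fixes_path and config.weather_path and config.meta_path):
        raise ConfigError("either a cohort or fixes/weather/meta paths are required")
    return (
        telemetry_io.read_fixes(config.fixes_path),
        telemetry_io.read_weather(config.weather_path),
        telemetry_io.read_meta(config.meta_path),
    )


def run_pipeline(config: PipelineConfig, cohort: synthetic.SimulatedCohort | None = None) -> PipelineReport:
    """Run the full analysis. Deterministic given config (incl. seed) + inputs."""
    config.validate()
    fixes, weather, meta = _load_inputs(config, cohort)
    fixes = telemetry_io.filter_accuracy(fixes, config.accuracy_keep)
    mort_params = config.mortality_params()
    dep_params = config.departure_params()

    fate_records: dict[str, mortality.FateRecord] = {}
    cov_rows = []
    premigration_fixes: dict[str, pd.DataFrame] = {}
    home_ranges: dict[str, space_use.HomeRange] = {}

    for _, m in meta.iterrows():
        ind = str(m["individual_id"])
        f = fixes[fixes["individual_id"] == ind]
        release = pd.Timestamp(m["release_timestamp"])
        try:
            rec = mortality.classify_mortality(f, weather, release, mort_params)
        except Exception as exc:  # noqa: BLE001 - surfaced with stage context
            raise StageError("mortality", ind, exc) from exc
        fate_records[ind] = rec
        end_date = mortality.fate_end_date(rec, release)
        try:
            call = migration.detect_departure(f, dep_params)
            stay = migration.stay_duration(release, call, fate_end_date=end_date)
        except Exception as exc:  # noqa: BLE001
            raise StageError("migration", ind, exc) from exc
        window_end = call.departure_date if call.departure_date is not None else end_date

        daily = daily_activity(f)
        release_date = local_date([release])[0]
        try:
            actavg = activity_average(
                daily[daily["individual_id"] == ind], (release_date, window_end), config.min_hours_per_day
            )
        except (ActivityWindowError, ValueError):
            actavg = np.nan

        pre = f[np.asarray(local_date(f["timestamp"])) < window_end]
        premigration_fixes[ind] = pre
        kde95 = np.nan
        try:
            hr = space_use.home_range(ind, pre, bandwidth=config.kde_bandwidth)
            home_ranges[ind] = hr
            kde95 = hr.kde95_area_km2
        except ValueError:
            log.warning("home range not estimable for %s", ind)

        wx = migration.premigration_weather(weather, window_end)
        cov_rows.append(
            {
                "individual_id": ind,
                "Releasetime": float(pd.Timestamp(release).dayofyear),
                "StayDur": float(stay.days),
                "migrated": stay.migrated,
                "departure_date": call.departure_date,
                "ActAvg": actavg,
                "KDE": kde95,
                "Weight": float(m["weight"]),
                "VISIB": float(wx["VISIB"]),
                "WDSP": float(wx["WDSP"]),
                "TEMP": float(wx["TEMP"]),
                "PRCP": float(wx["PRCP"]),
                "survival_days": rec.survival_days,
                "event": rec.event,
                "fate": rec.fate,
            }
        )

    covariates = pd.DataFrame(cov_rows)
    fates = pd.DataFrame(
        [
            {
                "individual_id": r.individual_id,
                "fate": r.fate,
                "survival_days": r.survival_days,
                "event": r.event,
                "death_time": r.death_time,
            }
            for r in fate_records.values()
        ]
    )

    km_curves, logrank_tests = _design_factor_survival(covariates, meta)
    clusters, morans = _spatial_stage(covariates, premigration_fixes, home_ranges, config)
    model_table, final_model, selection = _cox_stage(covariates, config)

    report = PipelineReport(
        covariates=covariates,
        fates=fates,
        km_curves=km_curves,
        logrank_tests=logrank_tests,
        clusters=clusters,
        morans=morans,
        model_table=model_table,
        final_model=final_model,
        config=config,
        fate_records=fate_records,
        selection=selection,
    )
    if config.output_dir:
        _write_report(report, config)
    return report


def _design_factor_survival(covariates: pd.DataFrame, meta: pd.DataFrame):
    df = covariates.merge(meta[["individual_id", *DESIGN_FACTORS]], on="individual_id")
    curve_rows, test_rows = [], []
    for factor in DESIGN_FACTORS:
        groups = df[factor].astype(str)
        curves = survival.km_fit(df["survival_days"], df["event"], groups)
        for lbl, c in curves.items():
            frame = c.to_frame()
            if frame.empty:  # no events in this group: flat S(t) = 1 curve
                frame = pd.DataFrame({"time": [0.0], "n_risk": [c.n], "n_events": [0], "survival": [1.0]})
            frame.insert(0, "factor", factor)
            frame.insert(1, "group", lbl)
            frame["median_survival"] = np.nan if c.median is None else float(c.median)
            curve_rows.append(frame)
        try:
            chi2, dof, p = survival.logrank_test(df["survival_days"], df["event"], groups)
            test_rows.append({"factor": factor, "chi2": chi2, "df": dof, "p": p})
        except ValueError as exc:
            test_rows.append({"factor": factor, "chi2": np.nan, "df": np.nan, "p": np.nan, "note": str(exc)})
    km_curves = pd.concat(curve_rows, ignore_index=True) if curve_rows else pd.DataFrame()
    return km_curves, pd.DataFrame(test_rows)


def _spatial_stage(covariates, premigration_fixes, home_ranges, config):
    ids, dist = space_use.individual_distance_matrix(premigration_fixes)
    clusters = pd.DataFrame()
    morans: dict = {"note": "not computed"}
    if len(ids) >= 2:
        labels, order, k = space_use.hierarchical_clusters(dist, config.cluster_linkage, config.cluster_k)
        clusters = pd.DataFrame({"individual_id": ids, "cluster": labels})
        clusters = clusters.merge(covariates[["individual_id", "survival_days", "event"]], on="individual_id")
        clusters["dendrogram_order"] = pd.Series(order).reindex(range(len(ids))).to_numpy()
    with_hr = [i for i in ids if i in home_ranges]
    if len(with_hr) >= 4:
        pts = np.array([home_ranges[i].kde50_centroid for i in with_hr])
        surv = covariates.set_index("individual_id").loc[with_hr, "survival_days"].to_numpy()
        try:
            w = space_use.inverse_distance_weights(pts)
            res = space_use.morans_I(surv, w, config.morans_permutations, seed=config.seed)
            morans = {
                "I": res.I,
                "expected_I": res.expected_I,
                "z": res.z,
                "p_norm": res.p_norm,
                "p_perm": res.p_perm,
                "n": res.n,
                "weights_scheme": w.scheme,
                "row_standardized": w.row_standardized,
            }
        except ValueError as exc:
            morans = {"note": str(exc)}
    return clusters, morans


def _cox_stage(covariates: pd.DataFrame, config: PipelineConfig):
    rows = covariates.dropna(subset=list(COX_CANDIDATES) + ["survival_days", "event"]).copy()
    empty_final = {"covariates": [], "note": "insufficient data"}
    if len(rows) < 5 or rows["event"].sum() < 2:
        return pd.DataFrame(), empty_final, None
    usable = [c for c in COX_CANDIDATES if rows[c].nunique() > 1]
    retained, dropped = survival.vif_screen(rows, usable, config.vif_threshold)
    try:
        sel = survival.model_select(rows, retained, delta_aic=config.delta_aic)
    except ValueError as exc:
        return pd.DataFrame(), {"covariates": [], "note": str(exc)}, None
    table = sel.table.copy()
    table["covariates"] = table["covariates"].map(lambda t: "+".join(t) if t else "(null)")
    final: dict = {
        "covariates": list(sel.final_covariates),
        "vif_dropped": [{"covariate": c, "vif": v} for c, v in dropped],
        "null_aic": sel.null_aic,
    }
    if sel.final is not None:
        fit = sel.final
        ph = survival.schoenfeld_test(fit, rows) if fit.n_events >= 3 else {}
        final.update(
            {
                "hr": dict(zip(fit.covariates, fit.hr.tolist())),
                "hr_ci": {c: [lo, hi] for c, lo, hi in zip(fit.covariates, fit.hr_ci_low, fit.hr_ci_high)},
                "p": dict(zip(fit.covariates, fit.p.tolist())),
                "aic": fit.aic,
                "concordance": fit.concordance,
                "global_score_p": fit.global_score_p,
                "schoenfeld_p": ph,
            }
        )
    return table, final, sel


def _write_report(report: PipelineReport, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.covariates.to_csv(out / "covariates.csv", index=False, float_format="%.6f")
    report.fates.to_csv(out / "fates.csv", index=False, float_format="%.6f")
    report.km_curves.to_csv(out / "km_curves.csv", index=False, float_format="%.6f")
    report.logrank_tests.to_csv(out / "logrank_tests.csv", index=False, float_format="%.6f")
    report.clusters.to_csv(out / "clusters.csv", index=False, float_format="%.6f")
    report.model_table.to_csv(out / "model_table.csv", index=False, float_format="%.6f")
    with open(out / "morans.json", "w") as fh:
        json.dump(report.morans, fh, indent=2, default=str)
    with open(out / "final_model.json", "w") as fh:
        json.dump(report.final_model, fh, indent=2, default=str)
    windows = {
        ind: {k: [[str(a), str(b)] for a, b in v] for k, v in rec.criteria_windows.items()}
        for ind, rec in report.fate_records.items()
    }
    with open(out / "criteria_windows.json", "w") as fh:
        json.dump(windows, fh, indent=2)
    provenance = {"config": config.to_dict(), "config_hash": config.config_hash()}
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(provenance, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# synthetic-mode validation
# ---------------------------------------------------------------------------

def simulate_and_validate(
    scenario: synthetic.ScenarioConfig | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Simulate a cohort, run the pipeline, and score it against ground truth.

    Thresholds: every fate recovered, death times within 24 h, departure
    dates within 1 day on average.
    """
    scenario = scenario or synthetic.ScenarioConfig()
    config = config or PipelineConfig(seed=scenario.seed)
    cohort = synthetic.simulate_cohort(scenario)
    if scenario.n_individuals == 0:
        return {"n": 0, "fate_accuracy": 1.0, "passed": True, "note": "empty cohort"}
    report = run_pipeline(config, cohort=cohort)
    truth = cohort.truth.individuals.set_index("individual_id")
    fates = report.fates.set_index("individual_id")

    confusion: dict[str, dict[str, int]] = {}
    correct = 0
    death_errors_h = []
    departure_errors_d = []
    for ind in truth.index:
        expected = TRUTH_TO_FATE[truth.loc[ind, "fate"]]
        got = fates.loc[ind, "fate"]
        confusion.setdefault(expected, {}).setdefault(got, 0)
        confusion[expected][got] += 1
        if expected == got:
            correct += 1
        if truth.loc[ind, "fate"] == "natural_death" and got == "dead_confirmed":
            err = (pd.Timestamp(fates.loc[ind, "death_time"]) - pd.Timestamp(truth.loc[ind, "death_time"]))
            death_errors_h.append(abs(err.total_seconds()) / 3600.0)
        t_dep = truth.loc[ind, "departure_date"]
        c_dep = report.covariates.set_index("individual_id").loc[ind, "departure_date"]
        if t_dep is not None and not pd.isna(t_dep) and c_dep is not None and not pd.isna(c_dep):
            departure_errors_d.append(abs((pd.Timestamp(c_dep) - pd.Timestamp(t_dep)).days))

    n = len(truth)
    fate_accuracy = correct / n
    max_death_err = max(death_errors_h) if death_errors_h else 0.0
    dep_mae = float(np.mean(departure_errors_d)) if departure_errors_d else 0.0
    passed = fate_accuracy == 1.0 and max_death_err <= 24.0 and dep_mae <= 1.0
    result = {
        "n": n,
        "fate_accuracy": fate_accuracy,
        "confusion": confusion,
        "n_death_times_checked": len(death_errors_h),
        "max_death_time_error_h": max_death_err,
        "departure_date_mae_d": dep_mae,
        "passed": bool(passed),
    }
    log.info("validation: %s", result)
    return result
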