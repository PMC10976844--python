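"""End-to-end pipeline: simulate -> ODBA -> DEE -> condition -> models -> survival.

`run_pipeline` executes the whole analysis on synthetic inputs generated
from a :class:`~odee.synthetic.SimConfig`, writes every intermediate table
as CSV, and emits a JSON manifest holding input hashes, the full config
snapshot, per-stage record counts (a deployed/recovered/retained attrition
report) and the headline model results.  The pipeline is a pure function
of (config, seed): identical manifests on re-runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import accelerometry, condition, dlw, models, survival
from .synthetic import (
    SECONDS_PER_DAY,
    SimConfig,
    expected_burst_window_odba,
    simulate_accel_trace,
    simulate_dlw_experiment,
    simulate_population,
    streams,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("odee.pipeline")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and record context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")


class PipelineConfig(BaseModel):
    """Configuration for a full synthetic-study pipeline run."""

    sim: SimConfig = Field(default_factory=SimConfig)
    outdir: str = "odee_run"
    # study design
    n_study_per_season_year: int = 5
    study_years: int = 2
    trace_days: Optional[int] = 3          # None -> draw from sim range
    collar_failure_rate: float = 0.15
    recapture_failure_rate: float = 0.10
    # module options
    midpoint_mode: str = "range"
    day_boundary: str = "midnight"
    energy_equivalent: float = dlw.ENERGY_EQUIV_KJ_PER_L
    molar_volume: float = dlw.MOLAR_VOLUME_L
    qc: dict = Field(default_factory=dict)
    gam_df: int = 10
    gam_alpha: Optional[float] = 50.0      # None -> generalized cross-validation
    cost_ages: tuple[float, ...] = (2.0, 9.0)
    cost_seasons: tuple[str, ...] = ("summer", "autumn")


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> str:
    data = df.to_csv(index=False, float_format="%.10g").encode()
    path.write_bytes(data)
    return _sha256(data)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, (pd.Timestamp,)):
        return str(obj)
    return obj


def _simulate_study(
    config: PipelineConfig, captures: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Deploy collars + DLW on a study subset of the final simulated years.

    Each study record runs the *full* measurement chain: a raw trace
    through the ODBA pipeline, and a dosing through the DLW estimator
    with QC, with collar/recapture failures drawn at the configured rates.
    """
    sim = config.sim
    st = streams(sim.seed)
    rng = st["study"]
    trace_rng = st["traces"]
    dlw_rng = st["dlw"]
    prof = sim.activity_profile

    years = sorted(captures["year"].unique())[-config.study_years:]
    rows = []
    attrition = {
        "collars": {"deployed": 0, "recovered": 0, "retained": 0},
        "dlw": {"dosed": 0, "recaptured": 0, "retained": 0},
    }
    exclusions = []
    for year in years:
        for season in condition.SEASONS:
            pool = captures[
                (captures["year"] == year)
                & (captures["season"] == season)
                & (captures["age"] >= 1)
            ]
            if pool.empty:
                continue
            take = min(config.n_study_per_season_year, len(pool))
            chosen = pool.sample(
                n=take, random_state=int(rng.integers(0, 2**31 - 1))
            )
            for cap in chosen.itertuples():
                rec = {
                    "individual_id": cap.individual_id,
                    "year": int(year),
                    "season": season,
                    "sex": cap.sex,
                    "age": float(cap.age),
                    "weight_kg": float(cap.weight_kg),
                    "lactated": bool(cap.reproductive_female),
                    "odba": np.nan,
                    "dee": np.nan,
                }

                # latent energetics truth for this individual-season
                beta = sim.true_scaling_exponents[season]
                alpha_s = sim.true_scaling_alpha[season]
                dee_mu = alpha_s * float(cap.weight_kg) ** beta
                if season == "spring" and cap.reproductive_female:
                    dee_mu += sim.repro_dee_offset_kj
                dee_true = dee_mu * float(
                    np.exp(rng.normal(0.0, sim.dee_noise_sd))
                )
                od_mu = sim.od_base
                if season == "summer":
                    od_mu *= float(
                        np.exp(prof.summer_age_odba_slope * (cap.age - 2))
                    )
                if season == "spring" and cap.reproductive_female:
                    od_mu *= prof.repro_odba_multiplier
                od_latent = od_mu * float(
                    np.exp(rng.normal(0.0, sim.od_noise_sd))
                )

                # --- accelerometry branch ---
                attrition["collars"]["deployed"] += 1
                recovered = rng.random() >= config.collar_failure_rate
                if recovered:
                    attrition["collars"]["recovered"] += 1
                    # collar activity level scaled so the expected daily
                    # ODBA equals the latent OD x DEE target
                    base_daily = (
                        prof.bouts_per_night
                        * prof.bout_duration_s
                        / SECONDS_PER_DAY
                    ) * expected_burst_window_odba(
                        prof.burst_amplitude_g,
                        prof.burst_freq_hz,
                        sim.sampling_rate,
                    )
                    amp = od_latent * dee_true / base_daily
                    days = config.trace_days or int(
                        rng.integers(
                            sim.deployment_days[0], sim.deployment_days[1] + 1
                        )
                    )
                    month = condition.SEASON_MONTH[season]
                    start = pd.Timestamp(
                        year=int(year), month=month, day=10, hour=12
                    )
                    deployment, _ = simulate_accel_trace(
                        sim,
                        rng=trace_rng,
                        individual_id=cap.individual_id,
                        season=season,
                        start=start,
                        deployment_days=days,
                        amplitude_multiplier=amp,
                    )
                    series = accelerometry.compute_odba(
                        deployment,
                        midpoint_mode=config.midpoint_mode,
                        day_boundary=config.day_boundary,
                    )
                    rec["odba"] = series.odba_i
                    attrition["collars"]["retained"] += 1
                else:
                    exclusions.append(
                        {
                            "individual_id": cap.individual_id,
                            "year": int(year),
                            "season": season,
                            "stage": "collar",
                            "reason": "collar_failure",
                        }
                    )

                # --- DLW branch ---
                attrition["dlw"]["dosed"] += 1
                recaptured = rng.random() >= config.recapture_failure_rate
                if recaptured:
                    attrition["dlw"]["recaptured"] += 1
                    rco2 = dee_true / (
                        config.energy_equivalent * config.molar_volume
                    )
                    n_mol = (
                        sim.body_water_fraction
                        * float(cap.weight_kg)
                        * 1000.0
                        / 18.015
                    )
                    t_final = float(rng.uniform(6.5, 9.5))
                    dosing, _ = simulate_dlw_experiment(
                        rco2,
                        n_mol,
                        t_final,
                        sim,
                        rng=dlw_rng,
                        individual_id=cap.individual_id,
                        season=season,
                        weight_kg=float(cap.weight_kg),
                    )
                    result = dlw.estimate_dee(
                        dosing,
                        thresholds=dlw.QcThresholds(**config.qc),
                        energy_equivalent=config.energy_equivalent,
                        molar_volume=config.molar_volume,
                    )
                    if result.retained:
                        rec["dee"] = result.dee_kj_day
                        attrition["dlw"]["retained"] += 1
                    else:
                        exclusions.append(
                            {
                                "individual_id": cap.individual_id,
                                "year": int(year),
                                "season": season,
                                "stage": "dlw_qc",
                                "reason": ",".join(result.qc_flags),
                            }
                        )
                else:
                    exclusions.append(
                        {
                            "individual_id": cap.individual_id,
                            "year": int(year),
                            "season": season,
                            "stage": "dlw",
                            "reason": "not_recaptured_in_window",
                        }
                    )
                rows.append(rec)
    records = pd.DataFrame(rows)
    return records, {"attrition": attrition, "exclusions": exclusions}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": json.loads(config.model_dump_json()),
        "stages": {},
        "hashes": {},
    }
    stage = "simulate"
    try:
        captures, truth = simulate_population(config.sim)
        if captures.empty:
            raise PipelineError(stage, "simulated population is empty")
        manifest["stages"][stage] = {"captures": int(len(captures))}

        stage = "study"
        records, study_meta = _simulate_study(config, captures)
        manifest["stages"][stage] = study_meta["attrition"]
        manifest["stages"][stage]["records"] = int(len(records))

        stage = "odba_dee_merge"
        records = models.attach_od(records)
        overlap = int(records["od"].notna().sum())
        manifest["stages"][stage] = {
            "odba_n": int(records["odba"].notna().sum()),
            "dee_n": int(records["dee"].notna().sum()),
            "overlap_n": overlap,
        }

        stage = "condition"
        captures = condition.attach_bci(captures)
        # OD-driven perturbation of next-season condition (generating link)
        sim = config.sim
        if overlap:
            mean_od = float(records["od"].mean(skipna=True))
            delta_bci = sim.od_bci_slope * (records["od"] - mean_od)
            for rec, dbci in zip(records.itertuples(), delta_bci):
                if not np.isfinite(dbci):
                    continue
                nxt_season, nxt_year = condition.next_season(
                    rec.season, rec.year
                )
                mask = (
                    (captures["individual_id"] == rec.individual_id)
                    & (captures["season"] == nxt_season)
                    & (captures["year"] == nxt_year)
                )
                if mask.any():
                    bl = captures.loc[mask, "body_length_mm"]
                    captures.loc[mask, "weight_kg"] *= np.exp(
                        dbci * np.log(bl)
                    )
            captures["bci"] = [
                condition.bci(w, bl)
                for w, bl in zip(
                    captures["weight_kg"], captures["body_length_mm"]
                )
            ]
        adj = condition.fit_bci_adjustment(
            captures,
            df=config.gam_df,
            alpha=config.gam_alpha,
            select_alpha=config.gam_alpha is None,
        )
        captures = condition.next_season_residuals(captures, adj)
        linked = captures.set_index(["individual_id", "season", "year"])
        keys = list(
            zip(records["individual_id"], records["season"], records["year"])
        )
        records["bci_res"] = [
            linked["bci_res"].get(k, np.nan) for k in keys
        ]
        records["next_bci_res"] = [
            linked["next_bci_res"].get(k, np.nan) for k in keys
        ]
        manifest["stages"][stage] = {
            "long_term_captures": int(len(captures)),
            "linked_next_season": int(records["next_bci_res"].notna().sum()),
        }

        stage = "models"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scaling_dee = models.fit_seasonal_allometry(records, "dee")
            scaling_odba = models.fit_seasonal_allometry(records, "odba")
            covar = models.covariation_test(records)
            nxt = models.regress_od_on_next_bci(records)
        spring = records[
            (records["season"] == "spring") & records["od"].notna()
        ]
        od_contrast = None
        if (
            spring["lactated"].nunique() == 2
            and spring.groupby("lactated").size().min() >= 2
        ):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gc = models.group_contrasts(spring, "od", "lactated")
            od_contrast = {
                "t_p": gc.t_p,
                "groups": gc.groups,
            }
        manifest["stages"][stage] = {
            "dee_exponents": scaling_dee.exponents["beta"].to_dict(),
            "odba_exponents": scaling_odba.exponents["beta"].to_dict(),
            "dee_pooled_exponent": scaling_dee.pooled_exponent,
            "covariation": covar.summary(),
            "next_bci": nxt.summary(),
            "spring_od_lactation_contrast": od_contrast,
        }

        stage = "survival"
        annual = (
            captures.groupby(["individual_id", "year"])
            .agg(
                age=("age", "first"),
                bci_res=("bci_res", "mean"),
                reproductive_female=("reproductive_female", "first"),
                survived=("survived", "first"),
            )
            .reset_index()
        )
        surface = survival.fit_survival_surface(annual)
        od_ok = records.dropna(subset=["od", "next_bci_res"])
        cost = None
        if "od" in nxt.fits and len(od_ok) >= 3:
            trend = (
                float(nxt.fits["od"].params[0]),
                float(nxt.fits["od"].params[1]),
            )
            od_range = (float(od_ok["od"].min()), float(od_ok["od"].max()))
            cost = survival.od_to_survival_cost(
                trend,
                surface,
                od_range,
                ages=config.cost_ages,
                seasons=config.cost_seasons,
            )
        manifest["stages"][stage] = {
            "badger_years": int(len(annual)),
            "coefficients": surface.coefficients(),
            "truth_coefficients": truth["survival_coefficients"],
        }

        stage = "write"
        manifest["hashes"]["captures.csv"] = _write_csv(
            captures, outdir / "captures.csv"
        )
        manifest["hashes"]["energetics_records.csv"] = _write_csv(
            records, outdir / "energetics_records.csv"
        )
        manifest["hashes"]["annual_survival.csv"] = _write_csv(
            annual, outdir / "annual_survival.csv"
        )
        if cost is not None:
            manifest["hashes"]["survival_cost.csv"] = _write_csv(
                cost, outdir / "survival_cost.csv"
            )
            manifest["stages"]["survival"]["cost_table"] = _jsonable(
                cost.drop(columns=["se"]).to_dict("records")
            )
        exclusions = pd.DataFrame(study_meta["exclusions"])
        if not exclusions.empty:
            manifest["hashes"]["exclusions.csv"] = _write_csv(
                exclusions, outdir / "exclusions.csv"
            )
    except PipelineError:
        (outdir / "FAILED").write_text(stage)
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with stage context
        (outdir / "FAILED").write_text(f"{stage}: {exc}")
        raise PipelineError(stage, str(exc)) from exc

    manifest = _jsonable(manifest)
    data = json.dumps(manifest, indent=2, sort_keys=True).encode()
    (outdir / "manifest.json").write_bytes(data)
    return manifest
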