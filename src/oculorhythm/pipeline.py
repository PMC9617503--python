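"""End-to-end pipeline: simulate -> fit -> DLMO -> compare -> classify -> report.

Every stage writes a plain CSV under the run directory so each can be
re-run or audited independently; a JSON manifest records the seed, the
configuration echo and a hash of every numeric output.  Identical
configuration and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import __version__, population
from .cosinor import diurnal_variation_test, fit_population, fits_frame, fit_from_row
from .dlmo import dlmo_relative
from .growth import association_stats, interval_deltas, scale_thresholds
from .io_model import CohortTable, read_cohort, write_cohort
from .reports import clock_time_table, dlmo_table, population_table
from .season import compare_seasons
from .synthetic import default_truth, generate_cohort

log = logging.getLogger("oculorhythm")

GROWTH_SCHEMES = ("seven_month", "annual")


@dataclass
class RunConfig:
    out_dir: str = "run"
    input_dir: str | None = None  # simulate when absent
    seed: int = 0
    n_participants: int = 24
    seasons: tuple[str, ...] = ("W1", "S")
    parameters: tuple[str, ...] | None = None
    n_boot: int = 0  # bootstrap CIs on population fits when > 0
    n_perm: int = 0  # permutation p on the diurnal test when > 0
    dlmo_threshold: float = 3.0
    growth_scheme: str = "seven_month"
    growth_months: float = 7.0
    hst_anchor: str | float = population.HST_ANCHOR_H
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.growth_scheme not in GROWTH_SCHEMES:
            raise ValueError(
                f"unknown growth scheme {self.growth_scheme!r}; expected one of {GROWTH_SCHEMES}")
        if self.dlmo_threshold <= 0:
            raise ValueError("DLMO threshold must be positive")
        if self.n_boot < 0 or self.n_perm < 0:
            raise ValueError("resample counts must be >= 0")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "seasons" in payload:
            payload["seasons"] = tuple(payload["seasons"])
        if "parameters" in payload and payload["parameters"] is not None:
            payload["parameters"] = tuple(payload["parameters"])
        return cls(**payload)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def fit_cohort(cohort: CohortTable, seasons, parameters=None,
               n_boot: int = 0, seed: int | None = None) -> pd.DataFrame:
    """Population + individual cosinor fits for every parameter-season."""
    parameters = parameters or sorted(cohort.measurements["parameter"].unique())
    all_fits = []
    for param in parameters:
        for season in seasons:
            data = cohort.slice(param, season)
            if data.empty:
                continue
            pop, individuals = fit_population(
                data, log_scale=(param == "MEL"),
                ci=n_boot > 0, n_boot=n_boot, seed=seed,
                parameter=param, season=season,
            )
            all_fits.append(pop)
            all_fits.extend(individuals)
    return fits_frame(all_fits)


def run_pipeline(config: RunConfig) -> str:
    """Execute the full pipeline; returns the run directory path."""
    t_start = time.time()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        t0 = time.time()

        def done():
            timings[name] = round(time.time() - t0, 3)
            log.info("stage %s finished in %.2f s", name, timings[name])
        return done

    # --- data ------------------------------------------------------------
    done = stage("data")
    if config.input_dir:
        cohort = read_cohort(config.input_dir)
        truth_df = None
    else:
        truth = default_truth(
            parameters=config.parameters, seasons=config.seasons,
            n_participants=config.n_participants, seed=config.seed,
        )
        cohort, truth_df = generate_cohort(truth)
        data_dir = os.path.join(out, "data")
        write_cohort(cohort, data_dir)
        truth_df.to_csv(os.path.join(data_dir, "truth.csv"), index=False)
    done()

    seasons = [s for s in config.seasons
               if s in set(cohort.measurements["season"])]

    # --- cosinor fits -----------------------------------------------------
    done = stage("fit")
    fits = fit_cohort(cohort, seasons, config.parameters,
                      n_boot=config.n_boot, seed=config.seed)
    fits.to_csv(os.path.join(out, "fits.csv"), index=False)
    diurnal_rows = []
    for (param, season), _ in fits.groupby(["parameter", "season"]):
        data = cohort.slice(param, season)
        try:
            res = diurnal_variation_test(
                data, log_scale=(param == "MEL"),
                n_perm=config.n_perm, seed=config.seed,
                parameter=param, season=season)
        except ValueError as exc:
            log.warning("diurnal test skipped for %s/%s: %s", param, season, exc)
            continue
        diurnal_rows.append({
            "parameter": param, "season": season, "F": res.statistic,
            "df_num": res.df_num, "df_den": res.df_den, "p_value": res.p_value,
            "p_permutation": res.p_permutation, "method": res.method,
        })
    pd.DataFrame(diurnal_rows).to_csv(os.path.join(out, "diurnal.csv"), index=False)
    done()

    pop_fits = fits[fits["scope"] == "population"]
    ind_fits = fits[fits["scope"] == "individual"]

    # --- DLMO -------------------------------------------------------------
    done = stage("dlmo")
    dlmo_rows = []
    hst_by_pid = dict(zip(cohort.participants["id"], cohort.participants["hst_clock"]))
    for _, row in fits[fits["parameter"] == "MEL"].iterrows():
        fit = fit_from_row(row)
        res = dlmo_relative(fit, threshold=config.dlmo_threshold)
        anchor = (config.hst_anchor if fit.scope == "population"
                  else hst_by_pid.get(fit.participant_id, config.hst_anchor))
        dlmo_rows.append({
            "scope": row["scope"], "participant_id": row["participant_id"],
            "season": row["season"], "dlmo_rel_h": res.dlmo_rel,
            "defined": res.defined, "reason": res.reason,
            "dlmo_clock": res.clock(anchor) if res.defined else "",
        })
    pd.DataFrame(dlmo_rows).to_csv(os.path.join(out, "dlmo.csv"), index=False)
    done()

    # --- season comparison ------------------------------------------------
    done = stage("compare")
    if {"W1", "S"} <= set(seasons):
        comparison = compare_seasons(
            ind_fits[ind_fits["season"] == "W1"], ind_fits[ind_fits["season"] == "S"])
        comparison.to_csv(os.path.join(out, "seasons.csv"), index=False)
        est = {
            param: {row["season"]: fit_from_row(row)
                    for _, row in grp.iterrows()}
            for param, grp in pop_fits.groupby("parameter")
            if {"W1", "S"} <= set(grp["season"])
        }
        clock_time_table(est, config.hst_anchor).to_csv(
            os.path.join(out, "report_clock.csv"), index=False)
    done()

    # --- growth -----------------------------------------------------------
    done = stage("growth")
    have = lambda p, s: not ind_fits[(ind_fits["parameter"] == p)
                                     & (ind_fits["season"] == s)].empty
    if have("AL", "W1") and have("AL", "S"):
        def season_map(param):
            outm: dict[str, dict] = {}
            sel = ind_fits[ind_fits["parameter"] == param]
            for _, row in sel.iterrows():
                outm.setdefault(row["season"], {})[str(row["participant_id"])] = \
                    fit_from_row(row)
            return outm

        al_map, cht_map = season_map("AL"), season_map("ChT")
        intervals = ["W1-S"]
        if "W2" in al_map:
            intervals += ["S-W2", "W1-W2"]
        thr = scale_thresholds(months=config.growth_months) \
            if config.growth_scheme == "seven_month" else scale_thresholds(months=12.0)
        records = interval_deltas(al_map, cht_map or None, intervals=tuple(intervals),
                                  thresholds=thr)
        records.to_csv(os.path.join(out, "growth.csv"), index=False)
        first = records[records["interval"] == "W1-S"]
        if len(first) >= 4 and first["delta_cht"].notna().all():
            assoc = association_stats(first)
            serializable = {}
            for key, val in assoc.items():
                if isinstance(val, pd.DataFrame):
                    serializable[key] = val.to_dict(orient="records")
                elif hasattr(val, "__dict__"):
                    serializable[key] = asdict(val)
                else:
                    serializable[key] = val
            with open(os.path.join(out, "growth_assoc.json"), "w") as fh:
                json.dump(serializable, fh, indent=2, default=str)
    done()

    # --- report + manifest --------------------------------------------------
    done = stage("report")
    pop_table = population_table(
        [fit_from_row(r) for _, r in pop_fits.iterrows()])
    pop_table.to_csv(os.path.join(out, "report_population.csv"), index=False)
    done()

    outputs = sorted(
        f for f in os.listdir(out)
        if f.endswith((".csv", ".json")) and f != "manifest.json"
    )
    manifest = {
        "package": "oculorhythm", "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "outputs": {f: _sha256(os.path.join(out, f)) for f in outputs},
        "timings_s": timings,
        "elapsed_s": round(time.time() - t_start, 3),
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
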