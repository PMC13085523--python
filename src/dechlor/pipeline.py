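"""End-to-end orchestration: simulate → balance → rates → eeq → biomarkers → correlate.

:class:`RunConfig` fully determines a run; the config (plus seed) is
serialized into the output directory so every artifact is reconstructible.
Outputs are plain CSV/JSON and are byte-identical across repeated runs with
the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import copies_table, read_qpcr
from .core import (
    ETHENE_SERIES,
    BottleConfig,
    MassSeries,
    PhaseBasis,
    default_registry,
    write_timeseries,
)
from .electron_balance import eeq_distribution
from .partitioning import three_phase_balance, two_phase_total_mass
from .rates import production_rate, treatment_rate
from .correlate import pca_significant, spearman_matrix
from .scenarios import (
    ARMS,
    material_properties,
    scenario_kd_table,
    scenario_params,
    synthetic_qpcr_frame,
)
from .simulator import simulate_microcosm

__all__ = ["RunConfig", "StageError", "run_pipeline"]

#: Default regression windows (days) per arm for ethene; methane uses one window.
DEFAULT_ETHENE_WINDOWS = {
    "no-material": (28.0, 44.0),
    "sand": (28.0, 44.0),
    "Char350": (28.0, 44.0),
    "Char500": (28.0, 44.0),
    "Char700": (46.0, 66.0),
    "Char900": (46.0, 66.0),
}
DEFAULT_METHANE_WINDOW = (20.0, 44.0)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class RunConfig:
    """Validated, serializable description of one pipeline run."""

    out_dir: str
    seed: int = 0
    arms: tuple[str, ...] = ARMS
    noise_cv: float = 0.05
    n_replicates: int = 2
    t_end: float = 80.0
    alpha: float = 0.05
    eeq_day: float = 46.0
    run_balance: bool = True
    run_rates: bool = True
    run_eeq: bool = True
    run_biomarkers: bool = True
    run_correlate: bool = True
    qpcr_path: str | None = None  # external qPCR CSV; None → synthetic
    ethene_windows: dict = field(default_factory=lambda: dict(DEFAULT_ETHENE_WINDOWS))
    methane_window: tuple[float, float] = DEFAULT_METHANE_WINDOW

    def validate(self) -> None:
        unknown = [a for a in self.arms if a not in ARMS]
        if unknown:
            raise ValueError(f"unknown arms {unknown}; available: {ARMS}")
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        missing = [a for a in self.arms if a not in self.ethene_windows]
        if missing:
            raise ValueError(f"no ethene window configured for arms {missing}")
        if self.qpcr_path is not None and not Path(self.qpcr_path).exists():
            raise ValueError(f"qpcr_path {self.qpcr_path!r} does not exist")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # identical runs to different dirs hash the same
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _log(fh, message: str) -> None:
    fh.write(message + "\n")
    print(message, file=sys.stderr)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns a summary dict (also written).

    Raises :class:`StageError` naming the failing stage. Stage toggles omit
    exactly that stage's outputs; downstream stages that depend on a skipped
    stage degrade gracefully (correlation needs rates and is skipped without
    them, with a log line).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = default_registry()
    kd_table = scenario_kd_table()
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "arms": list(config.arms),
    }
    with open(out / "run.log", "w") as log:
        _log(log, f"dechlor {__version__} | seed {config.seed} | "
                  f"config {config.config_hash()}")
        with open(out / "config.json", "w") as fh:
            json.dump(asdict(config), fh, indent=2, sort_keys=True, default=str)

        # --- simulate -----------------------------------------------------
        datasets = {}
        all_obs = []
        try:
            for i, arm in enumerate(config.arms):
                params = scenario_params(
                    arm, t_end=config.t_end, noise_cv=config.noise_cv,
                    n_replicates=config.n_replicates,
                )
                ds = simulate_microcosm(params, seed=config.seed * 1009 + i)
                datasets[arm] = ds
                for s in ds.observations:
                    all_obs.append(
                        type(s)(bottle_id=f"{arm}-{s.bottle_id.split('-')[-1]}",
                                compound=s.compound, points=s.points,
                                phase_basis=s.phase_basis)
                    )
            write_timeseries(all_obs, out / "observations.csv")
            _log(log, f"simulate: {len(datasets)} arms, "
                      f"{len(all_obs)} observed series")
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError(f"simulate: {exc}") from exc

        obs_by_arm_bottle: dict[tuple[str, str], dict[str, object]] = {}
        for arm, ds in datasets.items():
            for s in ds.observations:
                rep = s.bottle_id.split("-")[-1]
                obs_by_arm_bottle.setdefault((arm, rep), {})[s.compound] = s

        # --- balance ------------------------------------------------------
        if config.run_balance:
            try:
                rows = []
                for (arm, rep), series in obs_by_arm_bottle.items():
                    params = datasets[arm].params
                    nominal: dict[float, float] = {}
                    cum = 0.0
                    for dose in sorted(params.dose_schedule, key=lambda d: d.day):
                        if dose.compound in ETHENE_SERIES:
                            cum += dose.amount
                            nominal[dose.day] = cum
                    ce_series = [series[c] for c in ETHENE_SERIES]
                    for bp in three_phase_balance(
                        ce_series, kd_table, params.bottle, nominal, registry
                    ):
                        rows.append(
                            {
                                "arm": arm, "bottle": f"{arm}-{rep}", "day": bp.day,
                                "two_phase_mass": bp.measured_two_phase_sum,
                                "estimated_sorbed": bp.estimated_sorbed,
                                "nominal_added": bp.nominal_added,
                                "closure_fraction": bp.closure_fraction,
                            }
                        )
                pd.DataFrame(rows).to_csv(out / "balance.csv", index=False)
                _log(log, f"balance: {len(rows)} closure points")
            except Exception as exc:
                raise StageError(f"balance: {exc}") from exc

        # --- rates ----------------------------------------------------------
        rate_rows: list[dict] = []
        if config.run_rates:
            try:
                for arm in config.arms:
                    for compound, window in (
                        ("ethene", tuple(config.ethene_windows[arm])),
                        ("methane", tuple(config.methane_window)),
                    ):
                        ests = []
                        for rep in range(1, config.n_replicates + 1):
                            series = obs_by_arm_bottle[(arm, str(rep))][compound]
                            mass_points = tuple(
                                (d, two_phase_total_mass(v, registry[compound],
                                                         datasets[arm].params.bottle)
                                 if not c else 0.0, c)
                                for d, v, c in series.points
                            )
                            mass_series = MassSeries(
                                bottle_id=series.bottle_id, compound=compound,
                                points=mass_points,
                                phase_basis=PhaseBasis.two_phase_mass,
                            )
                            try:
                                ests.append(production_rate(mass_series, window))
                            except ValueError as err:
                                _log(log, f"rates: skip {arm}-{rep}/{compound}: {err}")
                        if ests:
                            tr = treatment_rate(ests)
                            for e in ests:
                                rate_rows.append(
                                    {
                                        "arm": arm, "bottle": f"{arm}-{e.bottle_id.split('-')[-1]}",
                                        "compound": compound,
                                        "day_start": window[0], "day_end": window[1],
                                        "slope": e.slope, "slope_se": e.slope_se,
                                        "r_squared": e.r_squared, "n_points": e.n_points,
                                        "treatment_mean": tr.mean,
                                        "treatment_half_range": tr.half_range,
                                    }
                                )
                pd.DataFrame(rate_rows).to_csv(out / "rates.csv", index=False)
                _log(log, f"rates: {len(rate_rows)} bottle fits")
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"rates: {exc}") from exc

        # --- electron balance ----------------------------------------------
        if config.run_eeq:
            try:
                rows = []
                for arm, ds in datasets.items():
                    tr = ds.true_state
                    idx = int(np.argmin(np.abs(tr.days - config.eeq_day)))
                    donors = [d for d in ds.params.dose_schedule
                              if d.compound == "lactate" and d.day <= tr.days[idx]]
                    products = {
                        "ethene": float(tr.dissolved["ethene"][idx] + tr.sorbed["ethene"][idx]),
                        "methane": float(tr.dissolved["methane"][idx]),
                        **{v: float(tr.vfa[v][idx]) for v in tr.vfa},
                    }
                    ledger = eeq_distribution(donors, products, registry)
                    for e in ledger.entries:
                        rows.append(
                            {
                                "arm": arm, "day": float(tr.days[idx]),
                                "product": e.compound, "amount_umol": e.amount_umol,
                                "eeq": e.eeq, "percent_of_donor": e.percent_of_donor,
                            }
                        )
                    rows.append(
                        {
                            "arm": arm, "day": float(tr.days[idx]),
                            "product": "unaccounted", "amount_umol": float("nan"),
                            "eeq": ledger.donor_eeq_total
                            * ledger.unaccounted_percent / 100.0,
                            "percent_of_donor": ledger.unaccounted_percent,
                        }
                    )
                pd.DataFrame(rows).to_csv(out / "eeq.csv", index=False)
                _log(log, f"eeq: ledger at day {config.eeq_day} for {len(datasets)} arms")
            except Exception as exc:
                raise StageError(f"eeq: {exc}") from exc

        # --- biomarkers -----------------------------------------------------
        if config.run_biomarkers:
            try:
                if config.qpcr_path is not None:
                    measurements = read_qpcr(config.qpcr_path)
                    frame_rows = []
                    for m in measurements:
                        arm = m.bottle_id.rsplit("-", 1)[0]
                        bottle = (scenario_params(arm).bottle
                                  if arm in ARMS else BottleConfig())
                        frame_rows.append((m, bottle))
                    qdf = pd.concat(
                        [copies_table([m], b) for m, b in frame_rows],
                        ignore_index=True,
                    )
                else:
                    raw = synthetic_qpcr_frame(seed=config.seed * 1009 + 97)
                    raw = raw[raw["bottle"].str.rsplit("-", n=1).str[0].isin(config.arms)]
                    parts = []
                    for arm, sub in raw.groupby(
                        raw["bottle"].str.rsplit("-", n=1).str[0], sort=True
                    ):
                        bottle = scenario_params(str(arm)).bottle
                        import io as _io
                        sub_path = _io.StringIO()
                        sub.to_csv(sub_path, index=False)
                        sub_path.seek(0)
                        parts.append(copies_table(read_qpcr(sub_path), bottle))
                    qdf = pd.concat(parts, ignore_index=True)
                qdf = qdf.sort_values(
                    ["bottle", "gene", "fraction", "day"]
                ).reset_index(drop=True)
                qdf.to_csv(out / "biomarkers.csv", index=False)
                _log(log, f"biomarkers: {len(qdf)} normalized measurements")
            except Exception as exc:
                raise StageError(f"biomarkers: {exc}") from exc

        # --- correlate ------------------------------------------------------
        if config.run_correlate:
            if not rate_rows:
                _log(log, "correlate: skipped (no rate estimates available)")
            else:
                try:
                    rates_df = pd.DataFrame(rate_rows)
                    mat = material_properties()
                    feat_rows = []
                    for arm in config.arms:
                        if not arm.startswith("Char"):
                            continue
                        for rep in range(1, config.n_replicates + 1):
                            row = {"observation": f"{arm}-{rep}"}
                            for compound, col in (("ethene", "ethene_rate"),
                                                  ("methane", "methane_rate")):
                                sel = rates_df[
                                    (rates_df["arm"] == arm)
                                    & (rates_df["compound"] == compound)
                                    & (rates_df["bottle"] == f"{arm}-{rep}")
                                ]
                                row[col] = float(sel["slope"].iloc[0]) if len(sel) else float("nan")
                            for prop in ("BET_surface_area_m2_g", "pore_size_nm",
                                         "conductivity_S_m", "EDC_mmol_e_g",
                                         "zeta_potential_mV", "O_wt_pct", "N_wt_pct",
                                         "H_C_ratio", "O_C_ratio"):
                                row[prop] = float(mat.loc[arm, prop])
                            for cmpd in ("PCE", "cis-DCE", "VC"):
                                row[f"Kd_{cmpd}"] = kd_table.kd(arm, cmpd)
                            feat_rows.append(row)
                    features = pd.DataFrame(feat_rows).set_index("observation")
                    if len(features) >= 4:
                        rho, pmat, tiers = spearman_matrix(features, response="ethene_rate")
                        rho.to_csv(out / "correlation_rho.csv")
                        pmat.to_csv(out / "correlation_p.csv")
                        tiers.to_csv(out / "correlation_tiers.csv")
                        pca = pca_significant(features, "ethene_rate", alpha=config.alpha)
                        if not pca.empty:
                            pca.scores.to_csv(out / "pca_scores.csv")
                            pca.loadings.to_csv(out / "pca_loadings.csv")
                            pd.DataFrame(
                                {"component": pca.scores.columns,
                                 "variance_fraction": pca.variance_explained}
                            ).to_csv(out / "pca_variance.csv", index=False)
                        summary["n_significant_vars"] = len(pca.variables)
                        _log(log, f"correlate: {features.shape[0]} obs x "
                                  f"{features.shape[1]} vars; "
                                  f"{len(pca.variables)} significant for PCA")
                    else:
                        _log(log, "correlate: skipped (<4 biochar observations)")
                except Exception as exc:
                    raise StageError(f"correlate: {exc}") from exc

        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        _log(log, "done")
    return summary
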