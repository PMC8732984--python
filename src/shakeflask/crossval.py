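"""Leave-one-out cross-validation, fit metrics and Monte-Carlo bands.

Goodness of fit is summarised by the coefficient of determination R² and the
normalized root-mean-square deviation (NRMSE, normalised by the maximum
observed value, matching the estimation objective's normalisation; mean- and
range-normalised variants are available). Prediction uncertainty is shown as
pointwise empirical 5%/95% quantile bands over Monte-Carlo simulations that
draw parameter vectors uniformly from the multi-start ensemble and perturb
the initial concentrations.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .radiative import FlaskGeometry, LightSetting, RadiativeParams
from .kinetics import CultureState, KineticParams, SamplingSchedule, simulate
from .estimation import EstimationResult, EstimationSpec, fit_growth_params

__all__ = [
    "FitMetrics",
    "PredictionBand",
    "CrossvalReport",
    "r_squared",
    "nrmse",
    "prediction_band",
    "band_coverage",
    "make_growth_split_plan",
    "run_loo_crossval",
]


@dataclass(frozen=True)
class FitMetrics:
    r_squared: float
    nrmse: float

    def __post_init__(self) -> None:
        if self.r_squared > 1 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")
        if self.nrmse < 0:
            raise ValueError("nrmse must be >= 0")


@dataclass
class PredictionBand:
    """Pointwise 5%/95% quantile envelope and mean of simulated trajectories."""

    t_grid: np.ndarray
    observables: dict  # name -> {"q05": array, "mean": array, "q95": array}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, d in self.observables.items():
            rows.append(
                pd.DataFrame(
                    {
                        "time_h": self.t_grid,
                        "observable": name,
                        "q05": d["q05"],
                        "mean": d["mean"],
                        "q95": d["q95"],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (SS_tot about the mean)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must be aligned")
    if obs.size < 2:
        raise ValueError("need at least 2 points")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observations have zero variance")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def nrmse(observed, predicted, norm: str = "max") -> float:
    """Root-mean-square deviation normalised by max (default), mean or range."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size == 0:
        raise ValueError("empty input")
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must be aligned")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if norm == "max":
        scale = float(np.max(obs))
    elif norm == "mean":
        scale = float(np.mean(obs))
    elif norm == "range":
        scale = float(np.max(obs) - np.min(obs))
    else:
        raise ValueError(f"unknown normalisation {norm!r}")
    if scale <= 0:
        raise ValueError(f"normalisation scale ({norm}) must be positive")
    return rmse / scale


def prediction_band(
    setting: LightSetting,
    param_samples: pd.DataFrame,
    initial_state: CultureState,
    rsd: float,
    n_sims: int,
    seed: int,
    t_grid,
    fixed_params: dict | None = None,
    rp: RadiativeParams | None = None,
    geometry: FlaskGeometry | None = None,
    sched: SamplingSchedule | None = None,
    method: str = "rk4",
) -> PredictionBand:
    """Monte-Carlo prediction band for one light setting.

    Each of ``n_sims`` trajectories uses a parameter vector drawn uniformly
    (with replacement) from the rows of ``param_samples`` — columns are a
    subset of (mu_max, mu_d, K_I, K_N, Y_NX), missing ones fall back to
    ``fixed_params`` — and initial concentrations perturbed with relative SD
    ``rsd``. Quantiles are empirical (linear interpolation, numpy default),
    so bands are reproducible bit-for-bit for a given seed.
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    if len(param_samples) == 0:
        raise ValueError("param_samples must be nonempty")
    rp = rp or RadiativeParams()
    geometry = geometry or FlaskGeometry()
    sched = sched or SamplingSchedule()
    fixed = dict(fixed_params or {})
    t_grid = np.asarray(t_grid, dtype=float)
    rng = np.random.default_rng([int(seed), 877])
    cols = [c for c in ("mu_max", "mu_d", "K_I", "K_N", "Y_NX") if c in param_samples.columns]

    X_all = np.empty((n_sims, t_grid.size))
    N_all = np.empty((n_sims, t_grid.size))
    for i in range(n_sims):
        row = param_samples.iloc[int(rng.integers(0, len(param_samples)))]
        d = {**fixed, **{c: float(row[c]) for c in cols}}
        kp = KineticParams(
            mu_max=d["mu_max"], mu_d=min(d["mu_d"], d["mu_max"]), K_I=d["K_I"],
            K_N=d["K_N"], Y_NX=d["Y_NX"],
        )
        X0 = max(initial_state.X * (1.0 + rng.normal(0.0, rsd)), 1e-9) if rsd > 0 else initial_state.X
        cN0 = max(initial_state.c_N * (1.0 + rng.normal(0.0, rsd)), 0.0) if rsd > 0 else initial_state.c_N
        traj = simulate(
            CultureState(X0, initial_state.V, cN0, initial_state.t),
            setting, kp, rp, geometry, sched, t_grid, method=method,
        )
        X_all[i] = traj["biomass_g_per_L"].to_numpy()
        N_all[i] = traj["nitrate_g_per_L"].to_numpy()

    obs = {}
    for name, arr in (("biomass_g_per_L", X_all), ("nitrate_g_per_L", N_all)):
        obs[name] = {
            "q05": np.quantile(arr, 0.05, axis=0),
            "mean": arr.mean(axis=0),
            "q95": np.quantile(arr, 0.95, axis=0),
        }
    return PredictionBand(t_grid=t_grid, observables=obs)


def band_coverage(band: PredictionBand, t_obs, values, observable: str = "biomass_g_per_L") -> float:
    """Fraction of observations lying inside the band at matching times."""
    t_obs = np.asarray(t_obs, dtype=float)
    values = np.asarray(values, dtype=float)
    idx = np.searchsorted(band.t_grid, t_obs)
    if not np.allclose(band.t_grid[idx], t_obs):
        raise ValueError("observation times must be on the band grid")
    lo = band.observables[observable]["q05"][idx]
    hi = band.observables[observable]["q95"][idx]
    return float(np.mean((values >= lo) & (values <= hi)))


def make_growth_split_plan(datasets, n_runs: int = 9, seed: int = 0) -> pd.DataFrame:
    """Build the leave-one-out run plan over one flask per light setting.

    One flask per setting is reserved as a test set and never trained on.
    Each run takes one flask from every setting (cycling through the
    remaining pool so flasks are used as evenly as possible); the flask of
    one setting — rotating with the run index — is the validation set, the
    others are training sets.
    """
    by_setting: dict[tuple, list] = {}
    for ds in datasets:
        by_setting.setdefault((ds.setting.I_S, ds.setting.L), []).append(ds.flask_id)
    settings = list(by_setting)
    rng = np.random.default_rng([int(seed), 409])
    test_ids = {}
    pools = {}
    for s in settings:
        ids = sorted(by_setting[s])
        t = ids[int(rng.integers(0, len(ids)))] if len(ids) > 1 else ids[0]
        if len(ids) == 1:
            raise ValueError(f"setting {s} has a single flask: cannot reserve a test set")
        test_ids[s] = t
        pools[s] = [i for i in ids if i != t]
    rows = []
    for run in range(n_runs):
        val_setting = settings[run % len(settings)]
        for s in settings:
            fid = pools[s][run % len(pools[s])]
            role = "validation" if s == val_setting else "train"
            rows.append({"run_id": run, "dataset_id": fid, "role": role})
    for s in settings:
        rows.append({"run_id": -1, "dataset_id": test_ids[s], "role": "test"})
    return pd.DataFrame(rows)


@dataclass
class CrossvalReport:
    pooled: EstimationResult
    validation: pd.DataFrame  # run_id, dataset_id, I_S, L, r2
    test: pd.DataFrame        # dataset_id, I_S, L, r2, nrmse
    diagonal: pd.DataFrame    # setting, time_h, observed, simulated
    spearman: dict            # {"intensity": (rho, p), "duration": (rho, p)}
    bands: dict = field(default_factory=dict)  # (I_S, L) -> PredictionBand


def run_loo_crossval(
    datasets,
    split_plan: pd.DataFrame,
    spec: EstimationSpec,
    geometry: FlaskGeometry | None = None,
    sched_template: SamplingSchedule | None = None,
    n_band_sims: int = 100,
    band_rsd: float = 0.03,
) -> CrossvalReport:
    """Full LOO cross-validation of the growth stage.

    Fits the growth parameters over the run plan, then evaluates each
    held-out test flask (one per light setting): R² and max-normalised NRMSE
    of the biomass prediction, a simulated-vs-observed diagonal table built
    from the Monte-Carlo band means, and Spearman rank correlations of NRMSE
    against light intensity and duration across settings.
    """
    geometry = geometry or FlaskGeometry()
    pooled = fit_growth_params(datasets, spec, split_plan, geometry)
    by_id = {d.flask_id: d for d in datasets}
    names = pooled.param_names
    kin_mean = {
        **{k: v for k, v in spec.fixed.items() if k in ("mu_max", "mu_d", "K_I", "K_N", "Y_NX")},
        **{n: float(pooled.mean[n]) for n in names},
    }
    rp = RadiativeParams(
        E_a=spec.fixed["E_a"], E_s=spec.fixed["E_s"], b=spec.fixed["b"],
        i0_coeffs=tuple(spec.fixed.get("i0_coeffs", RadiativeParams().i0_coeffs)),
    )

    # validation table
    vrows = []
    for run, r2 in pooled.extras["validation_r2"].items():
        sub = split_plan[(split_plan["run_id"] == run) & (split_plan["role"] == "validation")]
        fid = sub["dataset_id"].iloc[0]
        ds = by_id[fid]
        vrows.append({"run_id": run, "dataset_id": fid, "I_S": ds.setting.I_S,
                      "L": ds.setting.L, "r2": r2})
    validation = pd.DataFrame(vrows)

    # held-out test flasks, one per setting
    trows, drows, bands = [], [], {}
    for fid in pooled.extras["test_ids"]:
        ds = by_id[fid]
        t_obs = ds.data["time_h"].to_numpy(float)
        X_obs = ds.data["biomass_g_per_L"].to_numpy(float)
        sched = sched_template or SamplingSchedule(
            sample_times=ds.sample_times, V_sample=ds.V_sample, c_N_feed=ds.c_N_feed
        )
        kp = KineticParams(
            mu_max=kin_mean["mu_max"], mu_d=min(kin_mean["mu_d"], kin_mean["mu_max"]),
            K_I=kin_mean["K_I"], K_N=kin_mean["K_N"], Y_NX=kin_mean["Y_NX"],
        )
        init = CultureState(
            X=float(X_obs[0]), V=ds.V, c_N=_initial_nitrate(ds), t=float(t_obs[0])
        )
        band = prediction_band(
            ds.setting, pooled.samples[names], init, band_rsd, n_band_sims,
            seed=spec.seed + zlib.crc32(fid.encode()) % 100000, t_grid=t_obs,
            fixed_params=kin_mean, rp=rp, geometry=geometry, sched=sched,
        )
        bands[(ds.setting.I_S, ds.setting.L)] = band
        X_sim = band.observables["biomass_g_per_L"]["mean"]
        trows.append(
            {
                "dataset_id": fid, "I_S": ds.setting.I_S, "L": ds.setting.L,
                "r2": r_squared(X_obs, X_sim), "nrmse": nrmse(X_obs, X_sim),
            }
        )
        drows.append(
            pd.DataFrame(
                {
                    "dataset_id": fid, "I_S": ds.setting.I_S, "L": ds.setting.L,
                    "time_h": t_obs, "observed": X_obs, "simulated": X_sim,
                }
            )
        )
    test = pd.DataFrame(trows).sort_values(["I_S", "L"]).reset_index(drop=True)
    diagonal = pd.concat(drows, ignore_index=True)
    sp_i = stats.spearmanr(test["I_S"], test["nrmse"])
    sp_l = stats.spearmanr(test["L"], test["nrmse"])
    spearman = {
        "intensity": (float(sp_i.statistic), float(sp_i.pvalue)),
        "duration": (float(sp_l.statistic), float(sp_l.pvalue)),
    }
    return CrossvalReport(
        pooled=pooled, validation=validation, test=test, diagonal=diagonal,
        spearman=spearman, bands=bands,
    )


def _initial_nitrate(ds) -> float:
    if "nitrate_g_per_L" in ds.data.columns:
        v = ds.data["nitrate_g_per_L"].to_numpy(float)
        if np.isfinite(v[0]):
            return float(v[0])
    return float(ds.c_N0_nominal)
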