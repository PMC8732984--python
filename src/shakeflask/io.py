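"""Configuration, dataset containers, CSV readers/writers and run manifests.

All files are plain text. Units are encoded in the column names and enforced
at the boundary: times in hours, concentrations in g/L, intensities in
umol/(m2 s), heights in m, volumes in L.

File formats
------------
Cultivation CSV (one per flask): ``time_h, biomass_g_per_L, nitrate_g_per_L``
(the nitrate column may be empty for flasks without nitrate analytics).

Manifest CSV (one per fixture directory): one row per flask with columns
``flask_id, I_S_umol_m2_s, L_h, V_L, h_m, V_sample_L, c_N_feed_g_per_L,
c_N0_g_per_L, nitrate_measured, file``.

Light-scan CSV: ``I_S_umol_m2_s, z_m, X_g_per_L, I_local_umol_m2_s``.

Split-plan CSV: ``run_id, dataset_id, role`` with role train|validation|test.

Sampling convention: a sample (with medium replacement) is taken at every
observation time after the first, so readers reconstruct the sampling
schedule from the cultivation time column.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .radiative import FlaskGeometry, LightSetting, RadiativeParams
from .kinetics import KineticParams

__all__ = [
    "CultivationDataset",
    "ConfigError",
    "default_config",
    "load_config",
    "validate_config",
    "config_hash",
    "kinetics_from_config",
    "radiative_from_config",
    "geometry_from_config",
    "write_fixture_dir",
    "read_fixture_dir",
    "write_light_scans",
    "read_light_scans",
    "write_split_plan",
    "read_split_plan",
    "RunManifest",
]


class ConfigError(ValueError):
    """Configuration file violates the schema; the message names the field."""


@dataclass
class CultivationDataset:
    """One flask's observed time series plus its experimental metadata."""

    flask_id: str
    setting: LightSetting
    data: pd.DataFrame  # time_h, biomass_g_per_L[, nitrate_g_per_L]
    V: float = 0.2
    h: float = 0.04
    sample_times: tuple[float, ...] = ()
    V_sample: float = 0.0075
    c_N_feed: float = 1.0
    c_N0_nominal: float = 1.0
    nitrate_measured: bool = False

    def __post_init__(self) -> None:
        if "time_h" not in self.data.columns or "biomass_g_per_L" not in self.data.columns:
            raise ValueError(f"{self.flask_id}: cultivation data needs time_h and biomass_g_per_L")
        t = self.data["time_h"].to_numpy(float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError(f"{self.flask_id}: time_h must be strictly increasing, >= 2 points")
        self.sample_times = tuple(float(s) for s in self.sample_times)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """Hierarchical default configuration with explicit units in key names."""
    return {
        "seed": 0,
        "flask": {"h_m": 0.04, "V_L": 0.2},
        "radiative": {
            "E_a": 227.0,
            "E_s": 800.0,
            "b": 0.0008,
            "i0_coeffs": [6.92, 0.436, -8.1e-5],
        },
        "kinetics": {
            "mu_max": 0.135,
            "mu_d": 0.002,
            "K_I": 96.0,
            "K_N_g_per_L": 1.49e-4,
            "Y_NX": 0.245,
        },
        "schedule": {
            "mode": "impulsive",
            "V_sample_L": 0.0075,
            "c_N_feed_g_per_L": 1.0,
        },
        "design": {
            "duration_h": 240.0,
            "sampling_interval_h": 24.0,
            "X0_g_per_L": 0.1,
            "c_N0_g_per_L": 1.0,
            "noise_rsd": 0.03,
        },
        "estimation": {
            "n_restarts": 100,
            "perturb_rsd": 0.03,
            "objective_mode": "relative",
        },
    }


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load a YAML config merged over the defaults and validate it."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, overrides)
    validate_config(cfg)
    return cfg


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def validate_config(cfg: dict) -> None:
    def bad(key, msg):
        raise ConfigError(f"config field {key!r}: {msg}")

    def positive(section, key):
        v = cfg.get(section, {}).get(key)
        if not isinstance(v, (int, float)) or v <= 0:
            bad(f"{section}.{key}", f"must be a positive number, got {v!r}")

    positive("flask", "h_m")
    positive("flask", "V_L")
    positive("radiative", "E_a")
    positive("kinetics", "mu_max")
    positive("design", "duration_h")
    positive("design", "sampling_interval_h")
    rad = cfg.get("radiative", {})
    if rad.get("E_s", 0) < 0:
        bad("radiative.E_s", "must be >= 0")
    if not 0 <= rad.get("b", 0) <= 1:
        bad("radiative.b", "must be in [0, 1]")
    if len(rad.get("i0_coeffs", [])) != 3:
        bad("radiative.i0_coeffs", "must be a 3-element list [c0, c1, c2]")
    if cfg["schedule"].get("mode") not in ("impulsive", "continuous"):
        bad("schedule.mode", "must be 'impulsive' or 'continuous'")
    if cfg["design"].get("noise_rsd", 0) < 0:
        bad("design.noise_rsd", "must be >= 0")
    for i, s in enumerate(cfg["design"].get("settings", []) or []):
        if len(s) != 3:
            bad(f"design.settings[{i}]", "must be [I_S, L, n_flasks]")
        I_S, L, n = s
        if I_S < 0:
            bad(f"design.settings[{i}].I_S", "must be >= 0")
        if not 0 <= L <= 24:
            bad(f"design.settings[{i}].L", f"light duration must be in [0, 24] h, got {L}")
        if n < 1:
            bad(f"design.settings[{i}].n_flasks", "must be >= 1")


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=float).encode()).hexdigest()


def kinetics_from_config(cfg: dict) -> KineticParams:
    k = cfg["kinetics"]
    return KineticParams(
        mu_max=k["mu_max"], mu_d=k["mu_d"], K_I=k["K_I"],
        K_N=k["K_N_g_per_L"], Y_NX=k["Y_NX"],
    )


def radiative_from_config(cfg: dict) -> RadiativeParams:
    r = cfg["radiative"]
    return RadiativeParams(E_a=r["E_a"], E_s=r["E_s"], b=r["b"], i0_coeffs=tuple(r["i0_coeffs"]))


def geometry_from_config(cfg: dict) -> FlaskGeometry:
    return FlaskGeometry(V=cfg["flask"]["V_L"], h=cfg["flask"]["h_m"])


# ---------------------------------------------------------------------------
# Fixture directories (cultivations + manifest)
# ---------------------------------------------------------------------------

def write_fixture_dir(datasets, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ds in datasets:
        fname = f"{ds.flask_id}.csv"
        df = ds.data.copy()
        if "nitrate_g_per_L" not in df.columns:
            df["nitrate_g_per_L"] = np.nan
        df.to_csv(outdir / fname, index=False, float_format="%.10g")
        rows.append(
            {
                "flask_id": ds.flask_id,
                "I_S_umol_m2_s": ds.setting.I_S,
                "L_h": ds.setting.L,
                "V_L": ds.V,
                "h_m": ds.h,
                "V_sample_L": ds.V_sample,
                "c_N_feed_g_per_L": ds.c_N_feed,
                "c_N0_g_per_L": ds.c_N0_nominal,
                "nitrate_measured": ds.nitrate_measured,
                "file": fname,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False, float_format="%.10g")
    return outdir


def read_fixture_dir(indir) -> list[CultivationDataset]:
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    datasets = []
    for _, row in manifest.iterrows():
        df = pd.read_csv(indir / row["file"])
        t = df["time_h"].to_numpy(float)
        datasets.append(
            CultivationDataset(
                flask_id=str(row["flask_id"]),
                setting=LightSetting(I_S=float(row["I_S_umol_m2_s"]), L=float(row["L_h"])),
                data=df,
                V=float(row["V_L"]),
                h=float(row["h_m"]),
                sample_times=tuple(t[1:]),
                V_sample=float(row["V_sample_L"]),
                c_N_feed=float(row["c_N_feed_g_per_L"]),
                c_N0_nominal=float(row["c_N0_g_per_L"]),
                nitrate_measured=bool(row["nitrate_measured"]),
            )
        )
    return datasets


def write_light_scans(scans: pd.DataFrame, path) -> None:
    scans.to_csv(path, index=False, float_format="%.10g")


def read_light_scans(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"I_S_umol_m2_s", "z_m", "X_g_per_L", "I_local_umol_m2_s"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"light-scan file missing columns: {sorted(missing)}")
    return df


def write_split_plan(plan: pd.DataFrame, path) -> None:
    plan.to_csv(path, index=False)


def read_split_plan(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"run_id", "dataset_id", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"split plan missing columns: {sorted(missing)}")
    bad = set(df["role"]) - {"train", "validation", "test"}
    if bad:
        raise ConfigError(f"split plan has unknown roles: {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Traceability record: every output maps to a config + seed."""

    stage: str
    seed: int
    config_sha256: str
    inputs: dict = field(default_factory=dict)   # path -> sha256
    outputs: list = field(default_factory=list)
    notes: dict = field(default_factory=dict)

    @staticmethod
    def digest(path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    def write(self, path) -> None:
        from . import __version__

        payload = {
            "stage": self.stage,
            "seed": self.seed,
            "config_sha256": self.config_sha256,
            "package_version": __version__,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "notes": self.notes,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
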