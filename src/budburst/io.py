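"""CSV readers/writers and run configuration.

All tables are plain CSV with documented headers; DOY is 1-based
everywhere and dates, when given instead, are ISO-8601 and converted
leap-aware.  Floating-point output uses a fixed format so repeated runs
diff byte-identically.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

FLOAT_FORMAT = "%.6g"

WEATHER_REQUIRED = ["site", "year", "tmin", "tmean", "tmax"]
PHENO_REQUIRED = ["site", "year", "species", "seed_source", "tree", "bud",
                  "doy", "stage"]


def _doy_from_date(dates: pd.Series) -> pd.Series:
    parsed = pd.to_datetime(dates, format="%Y-%m-%d", errors="coerce")
    if parsed.isna().any():
        bad = list(dates.index[parsed.isna()][:5])
        raise ValueError(f"unparseable ISO dates at rows {bad}")
    return parsed.dt.dayofyear


def read_weather_csv(path) -> pd.DataFrame:
    """Typed, validated weather series (site, year, doy, tmin, tmean, tmax).

    Accepts either a ``doy`` column or an ISO ``date`` column (converted
    leap-aware).  Errors name offending rows (0-based data rows).
    """
    df = pd.read_csv(path)
    missing = [c for c in WEATHER_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"weather CSV missing columns: {missing}")
    if "doy" not in df.columns:
        if "date" not in df.columns:
            raise ValueError("weather CSV needs a 'doy' or 'date' column")
        df["doy"] = _doy_from_date(df["date"])
    for col in ("tmin", "tmean", "tmax"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = list(df.index[vals.isna()][:5])
            raise ValueError(f"non-numeric {col} at rows {bad}")
        df[col] = vals.astype(float)
    bad = df.index[df["tmin"] > df["tmax"]]
    if len(bad):
        raise ValueError(f"tmin > tmax at rows {list(bad[:10])}")
    df["doy"] = df["doy"].astype(int)
    df["year"] = df["year"].astype(int)
    return df[["site", "year", "doy", "tmin", "tmean", "tmax"]
              + (["logger"] if "logger" in df.columns else [])]


def write_weather_csv(weather: pd.DataFrame, path) -> None:
    weather.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_phenology_csv(path) -> pd.DataFrame:
    """Raw bud observations; stages restricted to 0..6 (or the merged
    label 12), censuses unique per bud."""
    df = pd.read_csv(path)
    missing = [c for c in PHENO_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"phenology CSV missing columns: {missing}")
    stages = pd.to_numeric(df["stage"], errors="coerce")
    ok = stages.between(0, 6) | (stages == 12)
    if stages.isna().any() or not ok.all():
        bad = list(df.index[stages.isna() | ~ok][:10])
        raise ValueError(f"stages must be integers 0..6 (or merged 12); bad rows {bad}")
    df["stage"] = stages.astype(int)
    df["doy"] = df["doy"].astype(int)
    df["year"] = df["year"].astype(int)
    key = ["site", "year", "species", "seed_source", "tree", "bud", "doy"]
    dup = df.duplicated(key)
    if dup.any():
        raise ValueError(f"duplicate (bud, doy) rows at {list(df.index[dup][:10])}")
    return df[PHENO_REQUIRED]


def write_phenology_csv(obs: pd.DataFrame, path) -> None:
    obs.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_SYNTH_KEYS = {"trees_per_group", "buds_per_tree", "sigma_tree", "sigma_year",
               "slope_per_day"}
_INPUT_KEYS = {"weather", "phenology", "reference_weather"}


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run.

    Exactly one of ``synthetic`` (generator settings) or ``inputs`` (paths
    to weather/phenology CSVs plus ``latitudes``) drives the run.  Unknown
    keys anywhere are rejected before any computation.
    """

    seed: int = 1
    output_dir: str = "budburst_out"
    synthetic: dict | None = None
    inputs: dict | None = None
    latitudes: dict | None = None
    encoding_mode: str = "strict"
    frost_pool_years: bool = True
    threshold: float = 0.51
    significance_multiplier: float = 1.96
    group_factor: str = "species"
    fit_method: str = "fast"
    refit_best: bool = True
    temperature_pool: list = field(default_factory=lambda: None)
    photoperiod_pool: list = field(default_factory=lambda: None)

    def __post_init__(self):
        if self.inputs is not None and self.synthetic is not None:
            raise ValueError("config must set either 'synthetic' or 'inputs', not both")
        if self.inputs is None and self.synthetic is None:
            self.synthetic = {}
        if self.synthetic is not None:
            unknown = set(self.synthetic) - _SYNTH_KEYS
            if unknown:
                raise ValueError(f"unknown synthetic keys: {sorted(unknown)}")
        if self.inputs is not None:
            unknown = set(self.inputs) - _INPUT_KEYS
            if unknown:
                raise ValueError(f"unknown inputs keys: {sorted(unknown)}")
            if "weather" not in self.inputs or "phenology" not in self.inputs:
                raise ValueError("inputs needs 'weather' and 'phenology' paths")
            if not self.latitudes:
                raise ValueError("file-based runs need site 'latitudes'")
        if self.encoding_mode not in ("strict", "cumulative"):
            raise ValueError(f"unknown encoding_mode {self.encoding_mode!r}")
        if self.fit_method not in ("fast", "full"):
            raise ValueError(f"unknown fit_method {self.fit_method!r}")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
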