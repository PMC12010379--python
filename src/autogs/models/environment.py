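"""Environment feature handling: the 11 daily weather variables, CSV
ingestion, and temporal aggregation into fixed-length feature vectors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Canonical order of the daily weather variables.
ENV_VARIABLES = (
    "tempmax",
    "tempmin",
    "humidity",
    "precip",
    "windspeed",
    "sealevelpressure",
    "cloudcover",
    "solarradiation",
    "solarenergy",
    "uvindex",
    "sunlightduration",
)

AGG_MODES = {"daily": 1, "weekly": 7, "biweekly": 14}


@dataclass
class EnvFeatureVector:
    env_id: str
    values: np.ndarray  # length 11 * n_bins, bin-major
    mode: str
    n_bins: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if len(self.values) != 11 * self.n_bins:
            raise ValueError(
                f"EnvFeatureVector length {len(self.values)} != 11 x {self.n_bins}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("EnvFeatureVector contains non-finite entries")


def read_env_csv(path) -> dict[str, pd.DataFrame]:
    """Read an environment series CSV (env,date,<11 variables>).

    Returns one date-sorted frame of the 11 variables per environment id.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = ["env", "date", *ENV_VARIABLES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"environment CSV {path!r} missing columns: {missing}")
    df["env"] = df["env"].astype(str)
    out = {}
    for env_id, grp in df.groupby("env", sort=True):
        grp = grp.sort_values("date").reset_index(drop=True)
        out[env_id] = grp[list(ENV_VARIABLES)].astype(float)
    return out


def aggregate_env(
    daily_series: pd.DataFrame | np.ndarray,
    mode: str = "weekly",
    window_days: int | None = None,
    env_id: str = "",
) -> EnvFeatureVector:
    """Aggregate a (days x 11) series into a flat feature vector.

    ``daily`` keeps every day; ``weekly``/``biweekly`` average 7/14-day
    bins, with a partial trailing bin averaged over its available days.
    The vector is bin-major: bin 0's 11 variables, then bin 1's, etc.
    """
    if mode not in AGG_MODES:
        raise ValueError(f"unknown aggregation mode {mode!r}; use one of {sorted(AGG_MODES)}")
    if isinstance(daily_series, pd.DataFrame):
        arr = daily_series[list(ENV_VARIABLES)].to_numpy(dtype=float)
    else:
        arr = np.asarray(daily_series, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 11:
        raise ValueError(f"daily series must be (days, 11), got {arr.shape}")
    if window_days is not None:
        if window_days < 1 or window_days > arr.shape[0]:
            raise ValueError(f"window_days {window_days} out of range for {arr.shape[0]} days")
        arr = arr[:window_days]
    step = AGG_MODES[mode]
    bins = [arr[i : i + step].mean(axis=0) for i in range(0, arr.shape[0], step)]
    mat = np.stack(bins)  # (n_bins, 11)
    return EnvFeatureVector(
        env_id=env_id, values=mat.ravel(), mode=mode, n_bins=mat.shape[0]
    )


def env_feature_matrix(
    series: dict[str, pd.DataFrame],
    env_ids: list[str],
    mode: str = "weekly",
    window_days: int | None = None,
) -> np.ndarray:
    """Stack per-sample environment vectors for a list of environment ids."""
    cache: dict[str, np.ndarray] = {}
    rows = []
    for e in env_ids:
        if e not in cache:
            if e not in series:
                raise KeyError(f"unknown environment id {e!r}")
            cache[e] = aggregate_env(series[e], mode=mode, window_days=window_days,
                                     env_id=e).values
        rows.append(cache[e])
    return np.stack(rows)
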