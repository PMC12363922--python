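"""Hourly binning, imputation and derived channels for the feature pipeline.

Raw timestamped vitals/labs are resampled onto an hourly grid ending at the
high-risk timestamp T0, missing bins are forward-filled up to 24 h and
otherwise mean-imputed from the training cohort, and three derived channels
are added per measurement channel: the encounter baseline (first observed
value), the local least-squares trend over a trailing window, and the time
since last measurement (TSLM) at T0.  The imputation mask is exposed as
extra binary channels so downstream models can distinguish observed from
filled values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RawTimeSeries",
    "FeatureConfig",
    "hourly_bin",
    "impute",
    "derive_baseline",
    "derive_trend",
    "derive_tslm",
    "tslm_channel",
    "encounter_features",
    "assemble_feature_matrix",
]

MASK_OBSERVED, MASK_FFILL, MASK_MEAN = 0, 1, 2
FFILL_LIMIT_H = 24.0  # forward-fill horizon


@dataclass
class RawTimeSeries:
    """One channel's measurements: sorted (time, value) pairs."""

    channel: str
    times: np.ndarray
    values: np.ndarray
    unit: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.channel}: times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.channel}: values must be finite")


@dataclass
class FeatureConfig:
    grid_hours: int = 24  # hourly bins before T0
    trend_window_h: float = 6.0


def hourly_bin(series: RawTimeSeries, start: float, t0: float) -> np.ndarray:
    """Mean of measurements per half-open hourly bin on [start, t0).

    Bin boundaries are aligned backward from t0; empty bins are NaN.
    """
    if t0 <= start:
        raise ValueError("window must be nonempty (start < t0)")
    n_bins = int(round(t0 - start))
    edges = t0 - np.arange(n_bins, -1, -1, dtype=float)  # start ... t0
    out = np.full(n_bins, np.nan)
    if series.times.size == 0:
        return out
    idx = np.digitize(series.times, edges) - 1
    for b in range(n_bins):
        sel = idx == b
        # [bin_start, bin_end) half-open: digitize(right=False) puts a point
        # equal to an edge into the bin starting at that edge, as required
        if np.any(sel):
            out[b] = series.values[sel].mean()
    return out


def impute(grid: np.ndarray, cohort_channel_mean: float) -> tuple[np.ndarray, np.ndarray]:
    """Fill missing bins: forward-fill while the last observation is at most
    24 h old, else substitute the (frozen) cohort channel mean.

    Returns (filled grid, mask) with mask codes 0=observed, 1=forward-filled,
    2=mean-imputed.
    """
    if not np.isfinite(cohort_channel_mean):
        raise ValueError("cohort mean must be finite")
    filled = grid.copy()
    mask = np.full(grid.shape, MASK_OBSERVED, dtype=np.int8)
    last_val, last_idx = np.nan, None
    for i, v in enumerate(grid):
        if np.isfinite(v):
            last_val, last_idx = v, i
            continue
        age_h = np.inf if last_idx is None else float(i - last_idx)
        if age_h <= FFILL_LIMIT_H:
            filled[i] = last_val
            mask[i] = MASK_FFILL
        else:
            filled[i] = cohort_channel_mean
            mask[i] = MASK_MEAN
    return filled, mask


def derive_baseline(series: RawTimeSeries, cohort_channel_mean: float) -> float:
    """First observed value in the encounter; cohort mean when never measured."""
    if series.times.size == 0:
        return float(cohort_channel_mean)
    return float(series.values[0])


def derive_trend(series: RawTimeSeries, t0: float, trend_window_h: float) -> float:
    """Least-squares slope (units/hour) over the trailing window before t0;
    0 when fewer than two points fall in the window."""
    sel = (series.times >= t0 - trend_window_h) & (series.times < t0)
    t, v = series.times[sel], series.values[sel]
    if t.size < 2 or np.ptp(t) == 0 or np.ptp(v) == 0:
        return 0.0
    tc = t - t.mean()
    return float((tc @ (v - v.mean())) / (tc @ tc))


def derive_tslm(series: RawTimeSeries, t0: float, window_h: float) -> float:
    """Hours from the last observation before t0 to t0; the window length
    when the channel was never observed."""
    before = series.times[series.times < t0]
    if before.size == 0:
        return float(window_h)
    return float(t0 - before[-1])


def tslm_channel(grid: np.ndarray, window_h: float | None = None) -> np.ndarray:
    """Per-bin time since last measurement, in hours.

    0 at bins with an observation; bins before the first observation get the
    window length (grid length when ``window_h`` is None)."""
    if window_h is None:
        window_h = float(grid.size)
    out = np.empty(grid.size)
    last = None
    for i, v in enumerate(grid):
        if np.isfinite(v):
            last = i
            out[i] = 0.0
        else:
            out[i] = window_h if last is None else float(i - last)
    return out


def encounter_features(
    series_by_channel: dict[str, RawTimeSeries],
    t0: float,
    cohort_means: dict[str, float],
    config: FeatureConfig,
) -> dict[str, float]:
    """Flat feature dict for one encounter (time-series part only)."""
    out: dict[str, float] = {}
    start = t0 - config.grid_hours
    for channel, mean in cohort_means.items():
        series = series_by_channel.get(
            channel, RawTimeSeries(channel, np.array([]), np.array([]))
        )
        grid = hourly_bin(series, start, t0)
        filled, mask = impute(grid, mean)
        for b in range(config.grid_hours):
            out[f"{channel}__h{b:02d}"] = float(filled[b])
        for b in range(config.grid_hours):
            out[f"{channel}__mask_h{b:02d}"] = float(mask[b] != MASK_OBSERVED)
        out[f"{channel}__baseline"] = derive_baseline(series, mean)
        out[f"{channel}__trend"] = derive_trend(series, t0, config.trend_window_h)
        out[f"{channel}__tslm"] = derive_tslm(series, t0, float(config.grid_hours))
    return out


def _series_maps(measurements: pd.DataFrame) -> dict[str, dict[str, RawTimeSeries]]:
    """Group the long measurements table into per-encounter channel maps."""
    out: dict[str, dict[str, RawTimeSeries]] = {}
    if measurements.empty:
        return out
    for (enc_id, channel), grp in measurements.groupby(["encounter_id", "channel"]):
        grp = grp.sort_values("time")
        t = grp["time"].to_numpy(dtype=float)
        v = grp["value"].to_numpy(dtype=float)
        keep = np.concatenate(([True], np.diff(t) > 0)) if t.size else np.array([], bool)
        out.setdefault(str(enc_id), {})[str(channel)] = RawTimeSeries(
            str(channel), t[keep], v[keep]
        )
    return out


def assemble_feature_matrix(
    encounters: pd.DataFrame,
    measurements: pd.DataFrame,
    static_cols: list[str] | None = None,
    config: FeatureConfig | None = None,
    cohort_means: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Build the model-ready feature table plus its column manifest.

    ``cohort_means`` freezes the per-channel means (training cohort) for
    mean imputation and baselines; when None they are computed from the
    provided measurements.  Column order is deterministic: per-channel
    blocks in sorted channel order, then statics.
    """
    config = config or FeatureConfig()
    if static_cols is None:
        static_cols = [
            c for c in encounters.columns
            if c not in ("encounter_id", "t0", "treatment", "imv", "mortality", "hospice")
        ]
    if cohort_means is None:
        cohort_means = {
            str(ch): float(grp["value"].mean())
            for ch, grp in measurements.groupby("channel")
        }
    cohort_means = dict(sorted(cohort_means.items()))

    all_maps = _series_maps(measurements)
    rows = []
    manifest: list[str] | None = None
    for _, enc in encounters.iterrows():
        smap = all_maps.get(str(enc["encounter_id"]), {})
        feats = encounter_features(smap, float(enc["t0"]), cohort_means, config)
        for c in static_cols:
            feats[c] = float(enc[c])
        if manifest is None:
            manifest = list(feats)
        elif list(feats) != manifest:
            raise ValueError("feature manifest mismatch across encounters")
        rows.append(feats)

    if manifest is None:  # empty cohort: full manifest, no rows
        dummy = encounter_features({}, 24.0, cohort_means, config)
        manifest = list(dummy) + list(static_cols)
    table = pd.DataFrame(rows, columns=manifest,
                         index=encounters["encounter_id"].to_numpy())
    return table, manifest
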