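"""Region summaries and wave scores for bisulfite read-count tracks.

A methylation track is a table of (chrom, pos, methylated_count,
unmethylated_count[, sample]). Region means average counts over positions
inside each 1-based inclusive interval (then across samples, when a track
carries several); regions whose mean methylated count exceeds a threshold
(default 700 reads, strict) are flagged as high-methylation regions.

"Methylation waves" — long-range, approximately periodic fluctuations of
methylated counts along the genome — are scored by an exploratory
detrended-autocorrelation statistic: the dominant period is the first
local autocorrelation maximum, the amplitude half the peak-to-trough
range of the smoothed detrended series. The scoring recipe is this
package's own operationalisation of the phenomenon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HIGH_METHYLATION_THRESHOLD = 700.0

TRACK_COLUMNS = ("chrom", "pos", "methylated_count", "unmethylated_count")


def _validate_track(track: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRACK_COLUMNS if c not in track.columns]
    if missing:
        raise ValueError(f"methylation track missing columns: {missing}")
    if (track["methylated_count"] < 0).any() or (track["unmethylated_count"] < 0).any():
        raise ValueError("read counts must be non-negative")
    return track


def region_mean_counts(track: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Mean methylated/unmethylated counts per region.

    ``regions`` needs columns (chrom, start, end) and optionally ``name``;
    intervals are 1-based inclusive. If the track has a ``sample`` column,
    positions are averaged within sample first, then across samples.
    Empty regions get NaN means and ``empty=True``.
    """
    track = _validate_track(track)
    rows = []
    for _, reg in regions.iterrows():
        sel = track[
            (track["chrom"].astype(str) == str(reg["chrom"]))
            & (track["pos"] >= int(reg["start"]))
            & (track["pos"] <= int(reg["end"]))
        ]
        name = reg["name"] if "name" in regions.columns else f"{reg['chrom']}:{reg['start']}-{reg['end']}"
        if sel.empty:
            rows.append({"name": name, "chrom": str(reg["chrom"]), "start": int(reg["start"]),
                         "end": int(reg["end"]), "mean_methylated": np.nan,
                         "mean_unmethylated": np.nan, "n_positions": 0, "empty": True})
            continue
        if "sample" in sel.columns:
            per = sel.groupby("sample")[["methylated_count", "unmethylated_count"]].mean()
            meth, unmeth = per["methylated_count"].mean(), per["unmethylated_count"].mean()
            n_pos = sel["pos"].nunique()
        else:
            meth = sel["methylated_count"].mean()
            unmeth = sel["unmethylated_count"].mean()
            n_pos = len(sel)
        rows.append({"name": name, "chrom": str(reg["chrom"]), "start": int(reg["start"]),
                     "end": int(reg["end"]), "mean_methylated": float(meth),
                     "mean_unmethylated": float(unmeth), "n_positions": int(n_pos),
                     "empty": False})
    return pd.DataFrame(rows)


def flag_high(region_table: pd.DataFrame, threshold: float = HIGH_METHYLATION_THRESHOLD) -> pd.DataFrame:
    """Regions whose mean methylated count strictly exceeds ``threshold``.

    A mean of exactly ``threshold`` is not flagged. Output is ordered by
    (chrom, start), independent of input row order.
    """
    flagged = region_table[region_table["mean_methylated"] > threshold]
    return flagged.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class WaveScore:
    period: float          # base pairs of the dominant fluctuation
    amplitude: float       # half peak-to-trough of the smoothed series
    acf_peak: float        # autocorrelation at the dominant lag


def wave_score(track: pd.DataFrame, window: tuple[int, int] | None = None) -> WaveScore | None:
    """Dominant period and amplitude of periodic methylation fluctuations.

    The methylated-count series (single-sample track, evenly interpolated
    over position if spacing is irregular) is linearly detrended — so the
    score is invariant to constant offsets — and its autocorrelation
    computed; the dominant period is the first local maximum lag with
    positive correlation. Returns None when there is too little data or
    no periodic structure.
    """
    track = _validate_track(track)
    if "sample" in track.columns and track["sample"].nunique() > 1:
        raise ValueError("wave_score expects a single-sample track (or mean track)")
    if window is not None:
        track = track[(track["pos"] >= window[0]) & (track["pos"] <= window[1])]
    track = track.sort_values("pos")
    pos = track["pos"].to_numpy(dtype=float)
    y = track["methylated_count"].to_numpy(dtype=float)
    if len(y) < 8:
        return None
    spacing = np.median(np.diff(pos))
    grid = np.arange(pos[0], pos[-1] + spacing / 2, spacing)
    y = np.interp(grid, pos, y)
    # Linear detrend.
    t = np.arange(len(y), dtype=float)
    coef = np.polyfit(t, y, 1)
    r = y - np.polyval(coef, t)
    if np.allclose(r, 0):
        return WaveScore(period=np.nan, amplitude=0.0, acf_peak=0.0)
    acf = np.correlate(r, r, mode="full")[len(r) - 1:]
    acf = acf / acf[0]
    # First local maximum after the initial dip.
    lag = None
    for k in range(1, len(acf) - 1):
        if acf[k] > acf[k - 1] and acf[k] >= acf[k + 1] and acf[k] > 0.1:
            lag = k
            break
    if lag is None:
        return WaveScore(period=np.nan, amplitude=0.0, acf_peak=0.0)
    # Smooth over a quarter period before measuring amplitude.
    w = max(3, lag // 4)
    kernel = np.ones(w) / w
    smooth = np.convolve(r, kernel, mode="same")
    amplitude = float((smooth.max() - smooth.min()) / 2.0)
    return WaveScore(period=float(lag * spacing), amplitude=amplitude, acf_peak=float(acf[lag]))


def mean_track(track: pd.DataFrame, samples: list[str] | None = None) -> pd.DataFrame:
    """Average a multi-sample track position-wise (optionally a subset)."""
    track = _validate_track(track)
    if samples is not None:
        track = track[track["sample"].isin(samples)]
    out = (
        track.groupby(["chrom", "pos"], sort=True)[["methylated_count", "unmethylated_count"]]
        .mean()
        .reset_index()
    )
    return out
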