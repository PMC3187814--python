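"""Introgression detection from two-genome comparative hybridization.

The scan follows the classical array-CGH chain: zoned background
subtraction, replicate normalization by a fitted through-origin slope,
per-probe log2 ratios of test over reference, an 11-probe sliding-window
average (roughly one gene on a yeast tiling design), segmentation of runs
of probes elevated above the genome-wide background, merging of elevated
runs separated by sub-kilobase gaps, and summarisation of regions larger
than a minimum size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

_MAD_TO_SD = 1.4826  # scales median absolute deviation to a normal sd


@dataclass(frozen=True)
class ProbeRecord:
    probe_id: str
    chrom: str
    start: int  # 1-based
    end: int    # inclusive
    intensity: float

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"probe {self.probe_id}: start > end")
        if self.intensity < 0:
            raise ValueError(f"probe {self.probe_id}: negative intensity")


class SignalTrack:
    """Ordered per-chromosome probe positions with one value per probe.

    Thin wrapper over a DataFrame with columns
    ``probe_id, chrom, start, end, value`` (plus optional ``telo_group``),
    sorted by (chrom, start).  ``value_kind`` is "intensity" or "log_ratio".
    """

    def __init__(self, df: pd.DataFrame, value_kind: str = "intensity"):
        required = {"probe_id", "chrom", "start", "end", "value"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"SignalTrack missing columns: {sorted(missing)}")
        if df["probe_id"].duplicated().any():
            dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValueError(f"duplicate probe_id: {dup}")
        self.df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        self.value_kind = value_kind

    @classmethod
    def from_intensities(cls, df: pd.DataFrame) -> "SignalTrack":
        if "intensity" not in df.columns:
            raise ValueError("probe table lacks an 'intensity' column")
        df = df.rename(columns={"intensity": "value"})
        if (df["value"] < 0).any():
            bad = df.index[df["value"] < 0][0]
            raise ValueError(f"negative intensity at row {bad}")
        return cls(df, value_kind="intensity")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def values(self) -> np.ndarray:
        return self.df["value"].to_numpy()

    def with_values(self, values: np.ndarray, value_kind: Optional[str] = None) -> "SignalTrack":
        df = self.df.copy()
        df["value"] = values
        return SignalTrack(df, value_kind or self.value_kind)

    def same_probes(self, other: "SignalTrack") -> None:
        a = self.df["probe_id"].to_numpy()
        b = other.df["probe_id"].to_numpy()
        if len(a) != len(b) or (a != b).any():
            if len(a) != len(b):
                raise ValueError(f"probe sets differ in size: {len(a)} vs {len(b)}")
            k = int(np.flatnonzero(a != b)[0])
            raise ValueError(f"probe mismatch at position {k}: {a[k]!r} vs {b[k]!r}")


@dataclass(frozen=True)
class ScanConfig:
    window_probes: int = 11
    gap_merge_bp: int = 1000
    min_region_bp: int = 1000
    threshold_k: float = 3.0
    zones: int = 16
    log_base: int = 2
    # lower bound on the estimated spread (log2 units): keeps the elevation
    # threshold meaningful on (near-)noiseless tracks where the MAD is 0,
    # i.e. a minimum detectable fold change of ~2**(3*0.05)
    min_spread: float = 0.05
    background_quantile: float = 0.02
    # floor after background subtraction, as a fraction of the track median;
    # a relative floor keeps the whole chain invariant to intensity rescaling
    floor_frac: float = 0.01
    # The 11-probe window is a display/summary smoother; segmentation runs on
    # the raw per-probe ratios by default so that region boundaries stay at
    # probe resolution.
    smooth_before_detect: bool = False

    def __post_init__(self):
        if self.window_probes < 1 or self.window_probes % 2 == 0:
            raise ValueError("window_probes must be odd and >= 1")
        if self.gap_merge_bp < 0 or self.min_region_bp < 0:
            raise ValueError("gap_merge_bp and min_region_bp must be >= 0")


@dataclass(frozen=True)
class IntrogressionRegion:
    chrom: str
    start: int
    end: int
    n_probes: int
    mean_log_ratio: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __post_init__(self):
        if self.length < 1 or self.n_probes < 1:
            raise ValueError("degenerate region")


def subtract_background(track: SignalTrack, config: ScanConfig = ScanConfig()) -> SignalTrack:
    """Zoned background subtraction.

    Probes are split (in genome order) into ``config.zones`` contiguous
    zones; each zone's background is the mean of its lowest 2% of
    intensities and each probe subtracts a background interpolated between
    zone centres, floored at a small positive value.
    """
    values = track.values.astype(float)
    n = len(values)
    if n == 0:
        return track.with_values(values)
    zones = config.zones
    if n < zones:
        warnings.warn("fewer probes than zones; falling back to a single zone", stacklevel=2)
        zones = 1
    bounds = np.linspace(0, n, zones + 1).astype(int)
    centers = np.empty(zones)
    bg = np.empty(zones)
    for z in range(zones):
        chunk = values[bounds[z]:bounds[z + 1]]
        k = max(1, int(np.ceil(config.background_quantile * len(chunk))))
        bg[z] = np.sort(chunk)[:k].mean()
        centers[z] = (bounds[z] + bounds[z + 1] - 1) / 2.0
    # a zone lying entirely inside a high-signal region reports the signal
    # itself as background; clamp zone estimates that are outliers relative
    # to the other zones (smooth background trends survive this)
    med_bg = float(np.median(bg))
    mad_bg = float(np.median(np.abs(bg - med_bg)))
    bg = np.minimum(bg, med_bg + 3.0 * _MAD_TO_SD * mad_bg)
    local_bg = np.interp(np.arange(n), centers, bg)
    floor = max(config.floor_frac * float(np.median(values)), 1e-12)
    corrected = np.maximum(values - local_bg, floor)
    return track.with_values(corrected)


def normalize_pair(rep1: SignalTrack, rep2: SignalTrack) -> Tuple[SignalTrack, float]:
    """Rescale the second replicate onto the first by a fitted slope.

    The slope is the least-squares regression through the origin of rep2 on
    rep1; rep2's values are divided by it so the two chips share a common
    scale before averaging.
    """
    rep1.same_probes(rep2)
    x = rep1.values.astype(float)
    y = rep2.values.astype(float)
    denom = float(np.dot(x, x))
    if denom == 0:
        raise ValueError("slope undefined: first replicate is all zeros")
    slope = float(np.dot(x, y)) / denom
    if slope == 0:
        raise ValueError("slope is zero; replicates are uncorrelated")
    return rep2.with_values(y / slope), slope


def average_tracks(tracks: List[SignalTrack]) -> SignalTrack:
    first = tracks[0]
    for t in tracks[1:]:
        first.same_probes(t)
    stacked = np.vstack([t.values for t in tracks])
    return first.with_values(stacked.mean(axis=0))


def compute_log_ratios(
    test: SignalTrack, reference: SignalTrack, config: ScanConfig = ScanConfig()
) -> SignalTrack:
    """Per-probe log2(test / reference)."""
    test.same_probes(reference)
    t = test.values.astype(float)
    r = reference.values.astype(float)
    if (t <= 0).any() or (r <= 0).any():
        raise ValueError("log ratio requires strictly positive intensities")
    return test.with_values(np.log2(t / r) / np.log2(config.log_base), value_kind="log_ratio")


def smooth(track: SignalTrack, w: int = 11) -> SignalTrack:
    """Centered per-chromosome moving average, truncated at chromosome ends."""
    if w % 2 == 0:
        raise ValueError("window must be odd")
    if w == 1:
        return track.with_values(track.values.copy())
    df = track.df
    out = np.empty(len(df))
    for _, idx in df.groupby("chrom", sort=False).indices.items():
        s = pd.Series(df["value"].to_numpy()[idx])
        out[idx] = s.rolling(w, center=True, min_periods=1).mean().to_numpy()
    return track.with_values(out)


def _merge_regions(
    regions: List[IntrogressionRegion], gap_bp: int
) -> List[IntrogressionRegion]:
    merged: List[IntrogressionRegion] = []
    for reg in regions:
        if merged and merged[-1].chrom == reg.chrom:
            gap = reg.start - merged[-1].end - 1
            if gap < gap_bp:
                prev = merged.pop()
                n = prev.n_probes + reg.n_probes
                mean = (
                    prev.mean_log_ratio * prev.n_probes
                    + reg.mean_log_ratio * reg.n_probes
                ) / n
                merged.append(
                    IntrogressionRegion(prev.chrom, prev.start, reg.end, n, mean)
                )
                continue
        merged.append(reg)
    return merged


def detect_regions(track: SignalTrack, config: ScanConfig = ScanConfig()) -> List[IntrogressionRegion]:
    """Call regions of probes elevated above the genome-wide background.

    The background level is the track median; spread is the MAD scaled to a
    normal sd.  Maximal runs of at least two consecutive probes exceeding
    median + k*spread become candidate regions, and candidates on the same
    chromosome separated by less than ``gap_merge_bp`` of genomic gap are
    merged (sub-kilobase gaps are treated as false-negative probes inside
    one contiguous introgression).  Probes sharing a ``telo_group`` label
    (telomere-repeat probes present at many chromosome ends) are counted
    once within a region.
    """
    df = track.df
    if len(df) == 0:
        return []
    values = track.values.astype(float)
    median = float(np.median(values))
    mad = float(np.median(np.abs(values - median)))
    spread = max(mad * _MAD_TO_SD, config.min_spread)
    elevated = values > median + config.threshold_k * spread
    regions: List[IntrogressionRegion] = []
    has_telo = "telo_group" in df.columns
    for chrom, idx in df.groupby("chrom", sort=False).indices.items():
        mask = elevated[idx]
        # maximal runs of consecutive elevated probes
        run_start = None
        for k in range(len(idx) + 1):
            on = k < len(idx) and mask[k]
            if on and run_start is None:
                run_start = k
            elif not on and run_start is not None:
                run = idx[run_start:k]
                run_start = None
                if len(run) < 2:
                    continue
                sub = df.iloc[run]
                if has_telo:
                    groups = sub["telo_group"]
                    keep = groups.isna() | ~groups.duplicated()
                    sub_unique = sub[keep]
                else:
                    sub_unique = sub
                regions.append(
                    IntrogressionRegion(
                        chrom=chrom,
                        start=int(sub["start"].iloc[0]),
                        end=int(sub["end"].iloc[-1]),
                        n_probes=len(sub_unique),
                        mean_log_ratio=float(sub_unique["value"].mean()),
                    )
                )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return _merge_regions(regions, config.gap_merge_bp)


def summarize_regions(
    regions: List[IntrogressionRegion], m: int = 1000
) -> Tuple[int, float]:
    """Count regions longer than ``m`` bp and their total length in kb."""
    big = [r for r in regions if r.length > m]
    total_kb = round(sum(r.length for r in big) / 1000.0, 1)
    return len(big), total_kb


def scan_pipeline(
    test_replicates: List[pd.DataFrame],
    reference_replicates: List[pd.DataFrame],
    config: ScanConfig = ScanConfig(),
) -> Tuple[SignalTrack, List[IntrogressionRegion]]:
    """Full chain from raw replicate intensity tables to called regions."""

    def prepare(replicates: List[pd.DataFrame]) -> SignalTrack:
        tracks = [
            subtract_background(SignalTrack.from_intensities(df), config)
            for df in replicates
        ]
        if len(tracks) >= 2:
            normed = [tracks[0]]
            for t in tracks[1:]:
                rescaled, _ = normalize_pair(tracks[0], t)
                normed.append(rescaled)
            tracks = normed
        return average_tracks(tracks)

    test = prepare(test_replicates)
    reference = prepare(reference_replicates)
    ratios = compute_log_ratios(test, reference, config)
    smoothed = smooth(ratios, config.window_probes)
    regions = detect_regions(smoothed if config.smooth_before_detect else ratios, config)
    return smoothed, regions
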