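"""SNP-index / delta-SNP-index genome scan for bulked-segregant analysis.

Given pooled allele counts for a high- and a low-phenotype bulk at every
parental-difference SNP, the scan computes per-site SNP-indices (fraction
of reads carrying the superior-parent allele; reference polarity is the
inferior parent), their difference delta = index_high - index_low, filters
out sites that look like sequencing/alignment artefacts (index < 0.3 in
both pools), smooths delta in sliding windows (50 kb window, 200 bp step
by default), derives a genome-wide top-quantile threshold from the window
means, and merges above-threshold windows into candidate QTL regions.

All genomic coordinates are 1-based inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScanConfig",
    "ScanResult",
    "compute_snp_index",
    "filter_sites",
    "compute_delta",
    "window_starts",
    "sliding_windows",
    "call_threshold",
    "call_regions",
    "scan",
]

HIGH = "HIGH"
LOW = "LOW"

SITE_COLUMNS = ["chrom", "pos", "high_ref", "high_alt", "low_ref", "low_alt"]


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters.

    window_size / step define the sliding-window grid (bp); index_cutoff is
    the both-pool SNP-index floor below which a site is treated as a false
    SNP; top_fraction sets the genome-wide threshold quantile over window
    means; min_depth_per_pool drops shallow sites (set 0 to disable — the
    original procedure applies no depth filter).
    """

    window_size: int = 50_000
    step: int = 200
    index_cutoff: float = 0.3
    top_fraction: float = 0.01
    min_depth_per_pool: int = 10
    include_putative: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.window_size:
            raise ValueError("require 0 < step <= window_size")
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must be in (0, 1)")
        if self.min_depth_per_pool < 0:
            raise ValueError("min_depth_per_pool must be >= 0")


@dataclass
class ScanResult:
    """All scan artefacts plus per-rule drop accounting."""

    sites: pd.DataFrame
    windows: pd.DataFrame
    threshold: float
    regions: pd.DataFrame
    drops: dict[str, int] = field(default_factory=dict)


def _wide_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Accept long (chrom,pos,pool_id,high_reads,low_reads) or wide
    (chrom,pos,high_ref,high_alt,low_ref,low_alt) count tables."""
    if set(SITE_COLUMNS) <= set(counts.columns):
        return counts.loc[:, [c for c in counts.columns if c in SITE_COLUMNS]].copy()
    required = {"chrom", "pos", "pool_id", "high_reads", "low_reads"}
    if not required <= set(counts.columns):
        raise ValueError(f"count table needs columns {sorted(required)} or {SITE_COLUMNS}")
    wide = counts.pivot_table(
        index=["chrom", "pos"],
        columns="pool_id",
        values=["high_reads", "low_reads"],
        aggfunc="sum",
    )
    out = pd.DataFrame({
        "high_ref": wide.get(("low_reads", HIGH)),
        "high_alt": wide.get(("high_reads", HIGH)),
        "low_ref": wide.get(("low_reads", LOW)),
        "low_alt": wide.get(("high_reads", LOW)),
    }).reset_index()
    return out


def compute_snp_index(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-site SNP-index for both pools: index = alt / (alt + ref).

    ``ref`` counts the inferior-parent (reference-polarity) allele and
    ``alt`` the superior-parent allele, so an index of 0 means every read
    came from the inferior parent and 1 means every read came from the
    superior parent. Sites with zero depth (or a missing record) in either
    pool are dropped; the number of drops is recorded in ``attrs``.
    """
    df = _wide_counts(counts)
    for c in ["high_ref", "high_alt", "low_ref", "low_alt"]:
        df[c] = df[c].fillna(0).astype(int)
        if (df[c] < 0).any():
            raise ValueError(f"negative read counts in column {c}")
    df["depth_high"] = df["high_ref"] + df["high_alt"]
    df["depth_low"] = df["low_ref"] + df["low_alt"]
    ok = (df["depth_high"] > 0) & (df["depth_low"] > 0)
    n_zero = int((~ok).sum())
    df = df.loc[ok].copy()
    df["index_high"] = df["high_alt"] / df["depth_high"]
    df["index_low"] = df["low_alt"] / df["depth_low"]
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    df.attrs["drops"] = {"zero_depth": n_zero}
    return df


def filter_sites(records: pd.DataFrame, config: ScanConfig = ScanConfig()) -> pd.DataFrame:
    """Apply the artefact filters.

    Sites with SNP-index below ``index_cutoff`` in BOTH pools are removed as
    presumed sequencing/alignment errors. Sites below the cutoff in exactly
    one pool are retained but flagged ``putative`` (set
    ``include_putative=False`` to drop them instead). Sites with depth below
    ``min_depth_per_pool`` in either pool are removed.
    """
    df = records.copy()
    drops = dict(df.attrs.get("drops", {}))

    deep = (df["depth_high"] >= config.min_depth_per_pool) & (
        df["depth_low"] >= config.min_depth_per_pool
    )
    drops["low_depth"] = int((~deep).sum())
    df = df.loc[deep]

    below_high = df["index_high"] < config.index_cutoff
    below_low = df["index_low"] < config.index_cutoff
    both_below = below_high & below_low
    drops["index_below_cutoff_both_pools"] = int(both_below.sum())
    df = df.loc[~both_below].copy()
    df["putative"] = (df["index_high"] < config.index_cutoff) ^ (
        df["index_low"] < config.index_cutoff
    )
    if not config.include_putative:
        drops["putative_excluded"] = int(df["putative"].sum())
        df = df.loc[~df["putative"]]
    df = df.reset_index(drop=True)
    df.attrs["drops"] = drops
    return df


def compute_delta(records: pd.DataFrame) -> pd.DataFrame:
    """delta = index_high - index_low, in [-1, 1]; high values mark loci
    preferentially inherited from the superior parent."""
    df = records.copy()
    df["delta"] = df["index_high"] - df["index_low"]
    df.attrs["drops"] = dict(records.attrs.get("drops", {}))
    return df


def window_starts(length: int, window_size: int, step: int) -> np.ndarray:
    """1-based window start grid: 1, 1+step, ... while the window fits, plus
    a final right-anchored window ending at the chromosome end."""
    if length < window_size:
        return np.array([1], dtype=int)
    last = length - window_size + 1
    starts = np.arange(1, last + 1, step, dtype=int)
    if starts[-1] != last:
        starts = np.append(starts, last)
    return starts


def sliding_windows(
    records: pd.DataFrame,
    chrom_lengths: dict[str, int],
    config: ScanConfig = ScanConfig(),
) -> pd.DataFrame:
    """Mean delta per sliding window.

    Windows span ``window_size`` bp and advance by ``step``; a chromosome
    shorter than the window yields a single clipped window flagged in the
    ``clipped`` column. ``mean_delta`` is the unweighted arithmetic mean of
    the deltas of member sites (start <= pos <= end); windows with no sites
    carry ``n_snps = 0`` and NaN mean and are excluded from thresholding.
    """
    frames = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        starts = window_starts(length, config.window_size, config.step)
        ends = np.minimum(starts + config.window_size - 1, length)
        sub = records.loc[records["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        delta = sub["delta"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos, delta = pos[order], delta[order]
        csum = np.concatenate([[0.0], np.cumsum(delta)])
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        n = hi - lo
        with np.errstate(invalid="ignore"):
            mean = np.where(n > 0, (csum[hi] - csum[lo]) / np.where(n > 0, n, 1), np.nan)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "n_snps": n.astype(int),
            "mean_delta": mean,
            "clipped": length < config.window_size,
        }))
    return pd.concat(frames, ignore_index=True)


def call_threshold(windows: pd.DataFrame, top_fraction: float = 0.01) -> float:
    """Genome-wide candidate-region threshold.

    The threshold is the smallest mean delta among the ceil(top_fraction*N)
    highest-ranked non-empty windows, i.e. the k-th order statistic from the
    top of the genome-wide window-mean distribution.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    means = windows.loc[windows["n_snps"] > 0, "mean_delta"].to_numpy()
    if means.size == 0:
        raise ValueError("no non-empty windows to threshold")
    k = math.ceil(top_fraction * means.size)
    return float(np.sort(means)[::-1][k - 1])


def call_regions(windows: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Merge above-threshold windows into candidate regions.

    Non-empty windows with mean delta >= threshold (ties at the cut are
    included) are grouped per chromosome; overlapping or book-ended windows
    merge into one region spanning min(start)..max(end). A gap of
    unflagged ground splits regions. The region mean is the mean of its
    member windows' means; regions are ranked by mean delta, descending.
    """
    flagged = windows.loc[(windows["n_snps"] > 0) & (windows["mean_delta"] >= threshold)]
    rows = []
    for chrom, grp in flagged.groupby("chrom", sort=False):
        grp = grp.sort_values("start", kind="stable")
        cur_start = cur_end = None
        members: list[float] = []
        for _, w in grp.iterrows():
            if cur_start is None:
                cur_start, cur_end, members = int(w["start"]), int(w["end"]), [w["mean_delta"]]
            elif w["start"] <= cur_end + 1:
                cur_end = max(cur_end, int(w["end"]))
                members.append(w["mean_delta"])
            else:
                rows.append((chrom, cur_start, cur_end, float(np.mean(members)), len(members)))
                cur_start, cur_end, members = int(w["start"]), int(w["end"]), [w["mean_delta"]]
        if cur_start is not None:
            rows.append((chrom, cur_start, cur_end, float(np.mean(members)), len(members)))
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_delta", "n_windows"])
    return regions.sort_values("mean_delta", ascending=False, kind="stable").reset_index(drop=True)


def scan(
    counts: pd.DataFrame,
    chrom_lengths: dict[str, int],
    config: ScanConfig = ScanConfig(),
) -> ScanResult:
    """Full scan: index -> filter -> delta -> windows -> threshold -> regions."""
    records = compute_snp_index(counts)
    records = filter_sites(records, config)
    records = compute_delta(records)
    windows = sliding_windows(records, chrom_lengths, config)
    threshold = call_threshold(windows, config.top_fraction)
    regions = call_regions(windows, threshold)
    return ScanResult(
        sites=records,
        windows=windows,
        threshold=threshold,
        regions=regions,
        drops=dict(records.attrs.get("drops", {})),
    )
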