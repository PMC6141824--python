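"""End-to-end pipeline: simulate (or load) pooled counts, scan, report.

A ``RunConfig`` (usually loaded from YAML) fully determines a run; under a
fixed global seed every stage draws from a deterministically derived
substream, so repeated runs produce byte-identical artefacts.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simcross
from .bsa import ScanConfig, ScanResult, scan
from .io import (
    read_allele_counts,
    write_counts_tsv,
    write_counts_vcf,
    write_regions,
    write_windows_tsv,
    write_yaml,
)

__all__ = ["SimConfig", "RunConfig", "simulate_cross", "run_pipeline"]

log = logging.getLogger("coldqtl")


@dataclass(frozen=True)
class SimConfig:
    """Synthetic-cross study conditions.

    Defaults mirror the mapping cross: 16 chromosomes of simulated markers,
    500 F2 haploid segregants, one major QTL lifting mumax from the inferior
    parent's 0.0025 h^-1 to the superior parent's 0.0132 h^-1 (effect
    0.0107), pools of the top 21 and bottom 23 segregants, 50x pooled
    sequencing.
    """

    n_chromosomes: int = 16
    chrom_length_bp: int = 200_000
    markers_per_chrom: int = 100
    n_segregants: int = 500
    cM_per_kb: float = 0.35
    qtl_chrom_index: int = 4  # 1-based; the major QTL sits mid-chromosome here
    qtl_beta: float = 0.0107
    mu0: float = 0.0025
    sigma: float = 0.001
    n_high: int = 21
    n_low: int = 23
    mean_depth: float = 50.0
    error_rate: float = 0.005

    def __post_init__(self) -> None:
        if not 1 <= self.qtl_chrom_index <= self.n_chromosomes:
            raise ValueError("qtl_chrom_index out of range")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a full run."""

    scan: ScanConfig = field(default_factory=ScanConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    counts_path: str | None = None  # when set, scan real counts instead of simulating
    counts_format: str | None = None
    chrom_lengths: dict[str, int] | None = None  # required with counts_path
    seed: int = 0
    polarity_flip: bool = False
    hi_threshold: float = 0.0135
    lo_threshold: float = 0.0030
    make_plot: bool = False

    def __post_init__(self) -> None:
        if self.counts_path is not None and not self.chrom_lengths:
            raise ValueError("chrom_lengths must be given when counts_path is set")
        if self.hi_threshold <= self.lo_threshold:
            raise ValueError("hi_threshold must exceed lo_threshold")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(raw) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        kwargs = dict(raw)
        if "scan" in kwargs and isinstance(kwargs["scan"], dict):
            kwargs["scan"] = ScanConfig(**kwargs["scan"])
        if "sim" in kwargs and isinstance(kwargs["sim"], dict):
            kwargs["sim"] = SimConfig(**kwargs["sim"])
        return cls(**kwargs)


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Deterministic per-stage 31-bit seeds derived from one global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def simulate_cross(sim: SimConfig, seed: int = 0):
    """Run the full synthetic cross; returns (marker_map, truth dict, counts).

    ``truth`` records segregant genotypes, phenotypes, pool membership and
    the planted QTL position for oracle checks.
    """
    s_map, s_seg, s_phen, s_seq = _stage_seeds(seed)
    chrom_spec = [(f"chr{i + 1:02d}", sim.chrom_length_bp) for i in range(sim.n_chromosomes)]
    marker_map = simcross.simulate_marker_map(chrom_spec, sim.markers_per_chrom, seed=s_map)

    qtl_chrom = chrom_spec[sim.qtl_chrom_index - 1][0]
    # plant the QTL at the marker closest to the chromosome midpoint
    positions = marker_map.markers[qtl_chrom]
    qtl_pos = int(positions[np.argmin(np.abs(positions - sim.chrom_length_bp // 2))])
    model = simcross.QTLModel(
        qtl_loci=((qtl_chrom, qtl_pos, sim.qtl_beta),), mu0=sim.mu0, sigma=sim.sigma
    )

    segregants = simcross.simulate_segregants(
        marker_map, simcross.CrossConfig(sim.n_segregants, sim.cM_per_kb, seed=s_seg)
    )
    phenotypes = simcross.assign_phenotypes(segregants, marker_map, model, seed=s_phen)
    hi_idx, lo_idx = simcross.select_pool_members(phenotypes, sim.n_high, sim.n_low)
    counts = simcross.sequence_pools(
        {"HIGH": hi_idx, "LOW": lo_idx},
        segregants,
        marker_map,
        simcross.SeqSimConfig(sim.mean_depth, sim.error_rate, seed=s_seq),
    )
    truth = {
        "segregants": segregants,
        "phenotypes": phenotypes,
        "high_pool": hi_idx,
        "low_pool": lo_idx,
        "qtl_chrom": qtl_chrom,
        "qtl_pos": qtl_pos,
    }
    return marker_map, truth, counts


def run_pipeline(config: RunConfig, outdir: str | Path) -> ScanResult:
    """Execute the configured stages and write all artefacts under outdir.

    Writes windows.tsv, regions.tsv, regions.bed, summary.yaml, the
    simulated counts (TSV + VCF) and truth tables in simulation mode, and
    optionally the per-chromosome scan plot.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    summary: dict = {"seed": config.seed, "polarity_flip": config.polarity_flip}

    if config.counts_path is not None:
        stage = "read counts"
        counts = read_allele_counts(config.counts_path, config.counts_format)
        chrom_lengths = dict(config.chrom_lengths)
        summary["counts_path"] = str(config.counts_path)
    else:
        stage = "simulate"
        marker_map, truth, counts = simulate_cross(config.sim, config.seed)
        chrom_lengths = dict(marker_map.chromosomes)
        write_counts_tsv(counts, outdir / "counts.tsv")
        write_counts_vcf(counts, marker_map, outdir / "counts.vcf")
        _write_truth(truth, marker_map, outdir)
        summary["qtl"] = {"chrom": truth["qtl_chrom"], "pos": truth["qtl_pos"]}
    log.info("stage %s done (%.1fs)", stage, time.perf_counter() - t0)

    if config.polarity_flip:
        counts = _flip_polarity(counts)

    try:
        result = scan(counts, chrom_lengths, config.scan)
    except Exception as exc:
        raise RuntimeError(f"scan stage failed: {exc}") from exc

    write_windows_tsv(result.windows, outdir / "windows.tsv")
    write_regions(result.regions, outdir / "regions.tsv", outdir / "regions.bed")
    n_sites_used = len(result.sites)
    summary.update({
        "sites_in": n_sites_used + sum(result.drops.values()),
        "drops": result.drops,
        "sites_used": n_sites_used,
        "n_windows": int(len(result.windows)),
        "n_nonempty_windows": int((result.windows["n_snps"] > 0).sum()),
        "threshold": float(result.threshold),
        "n_regions": int(len(result.regions)),
        "scan_config": asdict(config.scan),
    })
    if config.make_plot:
        from .plotting import plot_scan

        plot_scan(result.windows, result.threshold, outdir / "scan.png")
        summary["plot"] = "scan.png"
    summary["runtime_s"] = round(time.perf_counter() - t0, 3)
    write_yaml(summary, outdir / "summary.yaml")
    log.info("pipeline done: %d regions, threshold %.4f", len(result.regions), result.threshold)
    return result


def _flip_polarity(counts: pd.DataFrame) -> pd.DataFrame:
    """Swap parental roles (ref<->alt in both pools)."""
    df = counts.copy()
    if {"high_ref", "high_alt"} <= set(df.columns):
        df[["high_ref", "high_alt"]] = df[["high_alt", "high_ref"]].to_numpy()
        df[["low_ref", "low_alt"]] = df[["low_alt", "low_ref"]].to_numpy()
    else:
        df[["high_reads", "low_reads"]] = df[["low_reads", "high_reads"]].to_numpy()
    return df


def _write_truth(truth: dict, marker_map, outdir: Path) -> None:
    rows = []
    for chrom, _ in marker_map.chromosomes:
        geno = truth["segregants"][chrom]
        for j, pos in enumerate(marker_map.markers[chrom]):
            rows.append((chrom, int(pos), "".join(map(str, geno[:, j]))))
    pd.DataFrame(rows, columns=["chrom", "pos", "genotypes"]).to_csv(
        outdir / "truth_genotypes.tsv", sep="\t", index=False
    )
    phen = truth["phenotypes"]
    pool = np.full(len(phen), "NEITHER", dtype=object)
    pool[truth["high_pool"]] = "HIGH"
    pool[truth["low_pool"]] = "LOW"
    pd.DataFrame({
        "segregant": [f"seg{i:04d}" for i in range(len(phen))],
        "mumax": phen,
        "pool": pool,
    }).to_csv(outdir / "truth_phenotypes.tsv", sep="\t", index=False, float_format="%.6g")
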