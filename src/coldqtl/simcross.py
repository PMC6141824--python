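"""Synthetic biparental yeast cross with pooled sequencing.

Emulates the data-generating process behind a bulked-segregant QTL scan:
two divergent haploid parents, a panel of F2 haploid segregants produced
with Haldane (no-interference) recombination, growth phenotypes under an
additive major-QTL model anchored to the parents' maximum specific growth
rates at 4 degC, extreme-phenotype pools, and binomial short-read sampling
of each pool at every parental-difference marker.

Coordinates are 1-based throughout; a genotype of 1 means the superior
(high) parent's allele, 0 the inferior (low) parent's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "CrossConfig",
    "QTLModel",
    "SeqSimConfig",
    "simulate_marker_map",
    "simulate_segregants",
    "assign_phenotypes",
    "select_pool_members",
    "sequence_pools",
    "simulate_growth_series",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class MarkerMap:
    """Biallelic parental-difference markers on a set of chromosomes.

    ``markers[chrom]`` holds 1-based positions, strictly increasing.
    ``alleles[chrom]`` is a (n_markers, 2) array of (low-parent, high-parent)
    bases so that count tables can be written as a conventional VCF with the
    inferior parent as the reference polarity.
    """

    chromosomes: tuple[tuple[str, int], ...]
    markers: dict[str, np.ndarray]
    alleles: dict[str, np.ndarray]
    high_parent_label: str = "ZX11(6)"
    low_parent_label: str = "NX9(4)"

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for chrom, pos in self.markers.items():
            if chrom not in lengths:
                raise ValueError(f"markers on unknown chromosome {chrom!r}")
            pos = np.asarray(pos)
            if pos.size and (np.any(np.diff(pos) <= 0) or pos[0] < 1 or pos[-1] > lengths[chrom]):
                raise ValueError(f"marker positions on {chrom} not strictly increasing within bounds")

    @property
    def n_markers(self) -> int:
        return int(sum(len(p) for p in self.markers.values()))

    def marker_frame(self) -> pd.DataFrame:
        """All markers as a (chrom, pos, ref, alt) table in genomic order."""
        rows = []
        for chrom, _ in self.chromosomes:
            pos = self.markers.get(chrom, np.empty(0, dtype=int))
            al = self.alleles.get(chrom, np.empty((0, 2), dtype="U1"))
            for p, (ref, alt) in zip(pos, al):
                rows.append((chrom, int(p), ref, alt))
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


@dataclass(frozen=True)
class CrossConfig:
    """Meiosis parameters: segregant count and map density (cM per kb)."""

    n_segregants: int
    cM_per_kb: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segregants < 2:
            raise ValueError("n_segregants must be >= 2")
        if self.cM_per_kb < 0:
            raise ValueError("cM_per_kb must be >= 0")


@dataclass(frozen=True)
class QTLModel:
    """Additive QTL model: phenotype = mu0 + sum(beta * g) + N(0, sigma).

    ``mu0`` is the inferior parent's trait value; each locus adds ``beta``
    when the segregant carries the superior parent's allele (g = 1).
    Defaults anchor the two parents' maximum specific growth rates at 4 degC
    (0.0025 and 0.0132 h^-1), i.e. a single major QTL of effect 0.0107.
    """

    qtl_loci: tuple[tuple[str, int, float], ...] = ()
    mu0: float = 0.0025
    sigma: float = 0.001

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class SeqSimConfig:
    """Pooled-sequencing sampling model: Poisson depth, symmetric base error."""

    mean_depth: float = 50.0
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")


def simulate_marker_map(
    chrom_spec: list[tuple[str, int]],
    n_markers_per_chrom: int | dict[str, int],
    seed: int = 0,
    high_parent_label: str = "ZX11(6)",
    low_parent_label: str = "NX9(4)",
) -> MarkerMap:
    """Draw marker positions without replacement, uniformly per chromosome.

    Each marker gets a random pair of distinct bases (low-parent reference,
    high-parent alternative) so simulated counts can round-trip through VCF.
    """
    rng = np.random.default_rng(seed)
    markers: dict[str, np.ndarray] = {}
    alleles: dict[str, np.ndarray] = {}
    for chrom, length in chrom_spec:
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        n = n_markers_per_chrom[chrom] if isinstance(n_markers_per_chrom, dict) else n_markers_per_chrom
        if n < 1:
            raise ValueError("need at least one marker per chromosome")
        if n > length:
            raise ValueError(f"cannot place {n} markers on {length} bp of {chrom}")
        pos = np.sort(rng.choice(length, size=n, replace=False) + 1)
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        markers[chrom] = pos
        alleles[chrom] = np.stack([_BASES[ref_idx], _BASES[alt_idx]], axis=1)
    return MarkerMap(
        chromosomes=tuple((c, int(l)) for c, l in chrom_spec),
        markers=markers,
        alleles=alleles,
        high_parent_label=high_parent_label,
        low_parent_label=low_parent_label,
    )


def _morgans(length_bp: int, cM_per_kb: float) -> float:
    return length_bp * cM_per_kb / 1e5


def simulate_segregants(marker_map: MarkerMap, config: CrossConfig) -> dict[str, np.ndarray]:
    """Simulate haploid F2 genotypes at every marker.

    Returns one (n_segregants, n_markers) 0/1 array per chromosome.
    Meiosis follows the Haldane model: each chromosome receives a
    Poisson-distributed crossover count with mean equal to its genetic
    length in Morgans, crossover positions uniform, no interference; the
    starting parental phase of each chromosome is a fair coin flip.
    """
    if marker_map.n_markers == 0:
        raise ValueError("marker map has no markers")
    rng = np.random.default_rng(config.seed)
    genotypes: dict[str, np.ndarray] = {}
    for chrom, length in marker_map.chromosomes:
        pos = marker_map.markers.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        n = config.n_segregants
        geno = np.empty((n, len(pos)), dtype=np.int8)
        mean_xo = _morgans(length, config.cM_per_kb)
        phases = rng.integers(0, 2, size=n)
        n_xo = rng.poisson(mean_xo, size=n)
        for i in range(n):
            if n_xo[i] == 0:
                geno[i] = phases[i]
                continue
            breaks = np.sort(rng.uniform(0, length, size=n_xo[i]))
            # phase flips at every crossover left of the marker
            flips = np.searchsorted(breaks, pos)
            geno[i] = (phases[i] + flips) % 2
        genotypes[chrom] = geno
    return genotypes


def _locus_column(marker_map: MarkerMap, chrom: str, pos_bp: int) -> int:
    pos = marker_map.markers.get(chrom)
    if pos is None:
        raise ValueError(f"QTL chromosome {chrom!r} not in marker map")
    idx = np.searchsorted(pos, pos_bp)
    if idx >= len(pos) or pos[idx] != pos_bp:
        raise ValueError(f"QTL at {chrom}:{pos_bp} does not coincide with a marker")
    return int(idx)


def assign_phenotypes(
    segregants: dict[str, np.ndarray],
    marker_map: MarkerMap,
    qtl_model: QTLModel,
    seed: int = 0,
) -> np.ndarray:
    """Trait value (mumax, h^-1) per segregant under the additive model."""
    n = next(iter(segregants.values())).shape[0]
    mu = np.full(n, qtl_model.mu0, dtype=float)
    for chrom, pos_bp, beta in qtl_model.qtl_loci:
        geno = segregants.get(chrom)
        if geno is None:
            raise ValueError(f"QTL chromosome {chrom!r} not in genotypes")
        col = _locus_column(marker_map, chrom, pos_bp)
        mu += beta * geno[:, col]
    rng = np.random.default_rng(seed)
    if qtl_model.sigma > 0:
        mu = mu + rng.normal(0.0, qtl_model.sigma, size=n)
    return mu


def select_pool_members(
    phenotypes: np.ndarray,
    n_high: int = 21,
    n_low: int = 23,
    hi_threshold: float | None = None,
    lo_threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the two extreme pools.

    Either top/bottom-k selection (default, mirroring pools of 21 superior
    and 23 inferior segregants) or threshold-based selection when both
    thresholds are given (strict inequalities).
    """
    phen = np.asarray(phenotypes, dtype=float)
    if hi_threshold is not None or lo_threshold is not None:
        if hi_threshold is None or lo_threshold is None:
            raise ValueError("give both thresholds or neither")
        if hi_threshold <= lo_threshold:
            raise ValueError("hi_threshold must exceed lo_threshold")
        return np.flatnonzero(phen > hi_threshold), np.flatnonzero(phen < lo_threshold)
    order = np.argsort(phen, kind="stable")
    return order[::-1][:n_high], order[:n_low]


def sequence_pools(
    pools: dict[str, np.ndarray],
    segregants: dict[str, np.ndarray],
    marker_map: MarkerMap,
    config: SeqSimConfig,
) -> pd.DataFrame:
    """Sample pooled read counts at every marker for each pool.

    ``pools`` maps a pool id (e.g. ``"HIGH"``/``"LOW"``) to segregant row
    indices. Per site, depth ~ Poisson(mean_depth) and the high-parent read
    count ~ Binomial(depth, f(1-e) + (1-f)e) where f is the pool's
    high-allele frequency and e the symmetric error rate toward the other
    parental base.

    Returns a long table: chrom, pos, pool_id, high_reads, low_reads.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    for pool_id, members in pools.items():
        members = np.asarray(members)
        if members.size == 0:
            raise ValueError(f"pool {pool_id!r} is empty")
        for chrom, _ in marker_map.chromosomes:
            pos = marker_map.markers.get(chrom)
            if pos is None or len(pos) == 0:
                continue
            f = segregants[chrom][members].mean(axis=0)
            p = f * (1 - config.error_rate) + (1 - f) * config.error_rate
            depth = rng.poisson(config.mean_depth, size=len(pos))
            high = rng.binomial(depth, p)
            frames.append(pd.DataFrame({
                "chrom": chrom,
                "pos": pos.astype(int),
                "pool_id": pool_id,
                "high_reads": high,
                "low_reads": depth - high,
            }))
    return pd.concat(frames, ignore_index=True)


def simulate_growth_series(
    D: float,
    mumax: float,
    lam: float,
    schedule: np.ndarray | None = None,
    od0: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> "GrowthCurve":
    """Forward-simulate an OD600 time series from Gompertz parameters.

    The default ``schedule`` is a reading every 8 h for 18 days, as used for
    microplate growth assays at 4 degC. Noise is multiplicative Gaussian on
    the OD reading (proportional plate-reader error):
    OD_t = od0 * exp(y_t) * (1 + eps), eps ~ N(0, noise_sd).
    """
    from .growthfit import GrowthCurve, gompertz  # local import avoids a cycle

    if D <= 0 or mumax <= 0 or od0 <= 0:
        raise ValueError("D, mumax and od0 must be positive")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    t = np.arange(0, 18 * 24 + 1, 8, dtype=float) if schedule is None else np.asarray(schedule, dtype=float)
    y = gompertz(t, D, mumax, lam)
    od = od0 * np.exp(y)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od * (1 + rng.normal(0.0, noise_sd, size=od.shape))
    return GrowthCurve(times=t, od=od, blank_od=0.0)
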