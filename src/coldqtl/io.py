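"""Readers and writers for the scan's file formats.

Counts travel either as a wide TSV (chrom, pos, high_ref, high_alt,
low_ref, low_alt), a long TSV (chrom, pos, pool_id, high_reads, low_reads)
as written by the simulator, or a minimal VCF 4.2 with two pool samples
(HIGH_POOL, LOW_POOL) carrying allelic depths; the VCF REF allele is the
inferior-parent base and ALT the superior-parent base, matching the scan's
reference polarity. Gene annotation comes from GFF3 + FASTA; candidate
regions go out as BED (0-based half-open) and TSV.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO

from .bsa import HIGH, LOW, SITE_COLUMNS
from .simcross import MarkerMap
from .triage import GeneModel

__all__ = [
    "read_allele_counts",
    "write_counts_tsv",
    "write_counts_vcf",
    "read_annotation",
    "write_windows_tsv",
    "write_regions",
    "write_yaml",
]

log = logging.getLogger("coldqtl")

HIGH_SAMPLE = "HIGH_POOL"
LOW_SAMPLE = "LOW_POOL"


def read_allele_counts(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read pooled allele counts from VCF or TSV into the wide site table.

    ``fmt`` is inferred from the suffix when omitted (.vcf/.vcf.gz -> vcf,
    otherwise tsv). Multiallelic and indel VCF records are skipped and the
    skip counts logged; a sample without an AD field is an error.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if ".vcf" in path.suffixes or path.suffix == ".vcf" else "tsv"
    if fmt == "vcf":
        return _read_counts_vcf(path)
    if fmt == "tsv":
        return _read_counts_tsv(path)
    raise ValueError(f"unknown counts format {fmt!r}")


def _read_counts_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if set(SITE_COLUMNS) <= set(df.columns):
        return df[SITE_COLUMNS].copy()
    long_cols = {"chrom", "pos", "pool_id", "high_reads", "low_reads"}
    if long_cols <= set(df.columns):
        return df
    raise ValueError(
        f"{path}: TSV must have columns {SITE_COLUMNS} or {sorted(long_cols)}"
    )


def _read_counts_vcf(path: Path) -> pd.DataFrame:
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for s in (HIGH_SAMPLE, LOW_SAMPLE):
            if s not in samples:
                raise ValueError(f"{path}: VCF lacks pool sample {s!r}")
        if "AD" not in vcf.header.formats:
            raise ValueError(f"{path}: VCF FORMAT lacks AD")
        rows, n_multi, n_indel = [], 0, 0
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                n_multi += 1
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                n_indel += 1
                continue
            row = {"chrom": rec.chrom, "pos": rec.pos}
            for sample, prefix in ((HIGH_SAMPLE, "high"), (LOW_SAMPLE, "low")):
                ad = rec.samples[sample].get("AD")
                if ad is None or len(ad) != 2 or ad[0] is None:
                    raise ValueError(
                        f"{path}: missing AD for sample {sample} at {rec.chrom}:{rec.pos}"
                    )
                row[f"{prefix}_ref"], row[f"{prefix}_alt"] = int(ad[0]), int(ad[1])
            rows.append(row)
    if n_multi or n_indel:
        log.info("skipped %d multiallelic and %d indel records in %s", n_multi, n_indel, path)
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    """Write a counts table (long or wide) as TSV with a stable column order."""
    cols = SITE_COLUMNS if set(SITE_COLUMNS) <= set(counts.columns) else [
        "chrom", "pos", "pool_id", "high_reads", "low_reads"
    ]
    counts[cols].to_csv(path, sep="\t", index=False)


def write_counts_vcf(
    counts: pd.DataFrame,
    marker_map: MarkerMap,
    path: str | Path,
) -> None:
    """Write simulated pool counts as a two-sample VCF 4.2.

    REF is the low-parent allele, ALT the high-parent allele; each pool
    sample carries AD = (ref_reads, alt_reads).
    """
    from .bsa import _wide_counts  # normalised per-site table

    wide = _wide_counts(counts).set_index(["chrom", "pos"])
    alleles = marker_map.marker_frame().set_index(["chrom", "pos"])

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    for chrom, length in marker_map.chromosomes:
        header.contigs.add(chrom, length=length)
    header.add_sample(HIGH_SAMPLE)
    header.add_sample(LOW_SAMPLE)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for (chrom, pos), row in wide.sort_index().iterrows():
            ref, alt = alleles.loc[(chrom, pos), ["ref", "alt"]]
            rec = out.new_record(
                contig=chrom, start=pos - 1, stop=pos, alleles=(ref, alt), id=".",
            )
            rec.samples[HIGH_SAMPLE]["AD"] = (int(row["high_ref"]), int(row["high_alt"]))
            rec.samples[LOW_SAMPLE]["AD"] = (int(row["low_ref"]), int(row["low_alt"]))
            out.write(rec)


def read_annotation(
    gff_path: str | Path, fasta_path: str | Path
) -> tuple[list[GeneModel], dict[str, str]]:
    """Load gene models from GFF3 and chromosome sequences from FASTA.

    CDS features are grouped under their parent gene (via Parent chains or
    the gene's own CDS children) and ordered 5'->3' on the coding strand.
    Genes whose total CDS length is not a multiple of 3 are skipped with a
    warning; GFF seqids absent from the FASTA are an error.
    """
    genome = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    missing = sorted({f.seqid for f in db.all_features()} - genome.keys())
    if missing:
        raise ValueError(f"GFF seqids missing from FASTA: {missing}")

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        cds = list(db.children(gene, featuretype="CDS"))
        if not cds:
            continue
        intervals = sorted((c.start, c.end) for c in cds)
        if gene.strand == "-":
            intervals = intervals[::-1]
        total = sum(e - s + 1 for s, e in intervals)
        if total % 3 != 0:
            warnings.warn(
                f"skipping gene {gene.id}: CDS length {total} not divisible by 3",
                stacklevel=2,
            )
            continue
        models.append(
            GeneModel(gene_id=gene.id, chrom=gene.seqid, strand=gene.strand, cds=tuple(intervals))
        )
    return models, genome


def write_windows_tsv(windows: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end", "n_snps", "mean_delta"]
    windows[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_regions(regions: pd.DataFrame, tsv_path: str | Path, bed_path: str | Path | None = None) -> None:
    """Candidate regions as TSV (1-based inclusive) and BED (0-based half-open)."""
    cols = ["chrom", "start", "end", "mean_delta", "n_windows"]
    regions[cols].to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    if bed_path is not None:
        bed = regions.assign(start=regions["start"] - 1)
        bed["name"] = [f"region_{i + 1}" for i in range(len(bed))]
        bed[["chrom", "start", "end", "name", "mean_delta"]].to_csv(
            bed_path, sep="\t", index=False, header=False, float_format="%.6g"
        )


def write_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
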