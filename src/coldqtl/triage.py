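"""Candidate-gene triage inside a QTL region.

Three pieces of evidence are combined for every gene overlapping a
candidate region: whether each parental SNP in its coding sequence changes
the protein (synonymous vs non-synonymous, labelled in the conventional
``F396S`` form), and whether the superior parent's allele is absent from a
panel of independently sequenced strains (a parent-unique allele is a
strong causality hint — in the original cross only the CBS1 and NAT1
alleles of the superior parent were panel-unique).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "VariantEffect",
    "StrainPanel",
    "genes_in_region",
    "classify_variant_effect",
    "find_unique_alleles",
    "summarize_candidates",
    "load_strain_panel",
]

MISSING = "."


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: strand and CDS intervals.

    ``cds`` intervals are 1-based inclusive genomic (start, end) pairs,
    ordered 5'->3' along the coding strand (descending genomic order for a
    minus-strand gene). Total CDS length must be a multiple of 3.
    """

    gene_id: str
    chrom: str
    strand: str
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.cds:
            raise ValueError(f"{self.gene_id}: no CDS intervals")
        if self.cds_length % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3")
        spans = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping CDS intervals")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        """(min, max) genomic extent over the CDS intervals."""
        return min(s for s, _ in self.cds), max(e for _, e in self.cds)

    def coding_offset(self, pos: int) -> int | None:
        """0-based offset of a genomic position within the spliced CDS,
        measured along the coding strand; None if the position is non-coding."""
        off = 0
        for s, e in self.cds:
            if s <= pos <= e:
                return off + (pos - s if self.strand == "+" else e - pos)
            off += e - s + 1
        return None


@dataclass(frozen=True)
class VariantEffect:
    """Effect of a single-nucleotide substitution on a gene's protein."""

    gene_id: str
    chrom: str
    pos: int
    codon_index: int | None  # 1-based amino-acid position; None if non-coding
    ref_aa: str | None
    alt_aa: str | None
    synonymous: bool | None
    coding: bool

    @property
    def label(self) -> str:
        """Conventional protein-change label, e.g. ``F396S``; empty when
        synonymous or non-coding."""
        if not self.coding or self.synonymous:
            return ""
        return f"{self.ref_aa}{self.codon_index}{self.alt_aa}"


@dataclass(frozen=True)
class StrainPanel:
    """Allele matrix: rows = strains, columns = SNP positions.

    ``matrix`` cells hold single bases or ``"."`` for a missing (unknown)
    call. The two parents are ordinary rows identified by name.
    """

    matrix: pd.DataFrame  # index: strain names; columns: 1-based positions (int)
    genes: dict[int, str]  # position -> gene id
    chrom: str
    high_parent: str
    low_parent: str

    @property
    def panel_strains(self) -> list[str]:
        """Strains excluding the two parents."""
        return [s for s in self.matrix.index if s not in (self.high_parent, self.low_parent)]


def genes_in_region(
    gene_models: list[GeneModel], chrom: str, start: int, end: int
) -> list[GeneModel]:
    """Genes whose CDS span overlaps [start, end] by >= 1 bp, in genomic order."""
    hits = [
        g for g in gene_models
        if g.chrom == chrom and g.span[0] <= end and g.span[1] >= start
    ]
    return sorted(hits, key=lambda g: g.span)


def classify_variant_effect(
    gene: GeneModel,
    genome: dict[str, str],
    pos: int,
    ref: str,
    alt: str,
) -> VariantEffect:
    """Classify a single-base substitution against a gene model.

    The codon containing the site is extracted strand-aware (reverse
    complemented for minus-strand genes), the reference base is checked
    against the genome sequence, and both codons are translated with the
    standard nuclear genetic code. Sites outside the CDS are reported as
    non-coding. Multi-nucleotide variants and indels are rejected.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
        raise ValueError("only single-nucleotide A/C/G/T substitutions are supported")
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    seq = genome[gene.chrom]
    if not 1 <= pos <= len(seq):
        raise ValueError(f"position {pos} outside {gene.chrom}")
    if seq[pos - 1].upper() != ref:
        raise ValueError(
            f"reference mismatch at {gene.chrom}:{pos}: genome has {seq[pos - 1]!r}, variant says {ref!r}"
        )
    offset = gene.coding_offset(pos)
    if offset is None:
        return VariantEffect(gene.gene_id, gene.chrom, pos, None, None, None, None, coding=False)

    codon_idx, in_codon = divmod(offset, 3)
    cds_seq = _spliced_cds(gene, seq)
    if len(cds_seq) < 3 * (codon_idx + 1):
        raise ValueError(f"{gene.gene_id}: malformed model, partial codon at offset {offset}")
    codon = cds_seq[3 * codon_idx: 3 * codon_idx + 3]
    coding_ref = ref if gene.strand == "+" else str(Seq(ref).reverse_complement())
    coding_alt = alt if gene.strand == "+" else str(Seq(alt).reverse_complement())
    assert codon[in_codon] == coding_ref
    alt_codon = codon[:in_codon] + coding_alt + codon[in_codon + 1:]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return VariantEffect(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        pos=pos,
        codon_index=codon_idx + 1,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        synonymous=ref_aa == alt_aa,
        coding=True,
    )


def _spliced_cds(gene: GeneModel, chrom_seq: str) -> str:
    """Spliced CDS read 5'->3' along the coding strand. ``gene.cds`` is in
    coding order, so minus-strand intervals are reverse-complemented piecewise."""
    parts = []
    for s, e in gene.cds:
        piece = chrom_seq[s - 1: e].upper()
        parts.append(piece if gene.strand == "+" else str(Seq(piece).reverse_complement()))
    return "".join(parts)


def find_unique_alleles(panel: StrainPanel, focal_strain: str) -> pd.DataFrame:
    """Positions where the focal strain's allele occurs in no panel strain.

    A position counts as unique iff no non-parent strain with a non-missing
    call carries the focal allele there; missing cells are unknowns and
    never count as matches (so uniqueness claims cannot rest on absent
    data). Returns a (pos, gene, allele) table.
    """
    if focal_strain not in panel.matrix.index:
        raise ValueError(f"focal strain {focal_strain!r} not in panel")
    focal = panel.matrix.loc[focal_strain]
    others = panel.matrix.loc[panel.panel_strains]
    rows = []
    for pos in panel.matrix.columns:
        allele = focal[pos]
        if allele == MISSING:
            continue
        if not (others[pos] == allele).any():
            rows.append((int(pos), panel.genes[int(pos)], allele))
    return pd.DataFrame(rows, columns=["pos", "gene", "allele"])


def summarize_candidates(
    effects: list[VariantEffect],
    unique_positions: pd.DataFrame | None = None,
    region_genes: list[GeneModel] | None = None,
) -> pd.DataFrame:
    """Per-gene candidate table.

    One row per gene carrying at least one non-synonymous coding SNP (plus
    any extra genes in ``region_genes``): non-synonymous count, the protein
    change labels, and how many of the gene's positions carry a
    parent-unique allele. Sorted by unique-allele count, then
    non-synonymous count, both descending.
    """
    per_gene: dict[str, dict] = {}
    for g in region_genes or []:
        per_gene[g.gene_id] = {"gene": g.gene_id, "n_nonsyn": 0, "labels": [], "n_unique": 0}
    for eff in effects:
        row = per_gene.setdefault(
            eff.gene_id, {"gene": eff.gene_id, "n_nonsyn": 0, "labels": [], "n_unique": 0}
        )
        if eff.coding and not eff.synonymous:
            row["n_nonsyn"] += 1
            row["labels"].append(eff.label)
    if unique_positions is not None:
        for gene, grp in unique_positions.groupby("gene"):
            row = per_gene.setdefault(
                gene, {"gene": gene, "n_nonsyn": 0, "labels": [], "n_unique": 0}
            )
            row["n_unique"] = len(grp)
    if not per_gene:
        return pd.DataFrame(columns=["gene", "n_nonsyn", "labels", "n_unique"])
    df = pd.DataFrame(
        [{**r, "labels": ",".join(r["labels"])} for r in per_gene.values()],
        columns=["gene", "n_nonsyn", "labels", "n_unique"],
    )
    return df.sort_values(
        ["n_unique", "n_nonsyn", "gene"], ascending=[False, False, True], kind="stable"
    ).reset_index(drop=True)


def load_strain_panel(
    path: str | None = None,
    chrom: str = "chrIV",
    high_parent: str = "ZX11(6)",
    low_parent: str = "NX9(4)",
) -> StrainPanel:
    """Load a strain-panel allele matrix TSV.

    The format is two header rows (``gene`` then ``pos``) followed by one
    row per strain; ``#`` lines are comments; ``.`` marks missing cells.
    With no ``path``, the packaged chromosome-IV candidate-region panel
    (21 genes, 30 non-synonymous SNP positions, 2 parents + 28 sequenced
    strains) is loaded.
    """
    if path is None:
        ref = resources.files("coldqtl.data").joinpath("strain_panel.tsv")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = [ln.rstrip("\n") for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    gene_row = lines[0].split("\t")
    pos_row = lines[1].split("\t")
    if gene_row[0] != "gene" or pos_row[0] != "pos":
        raise ValueError("panel file must start with 'gene' and 'pos' header rows")
    genes = gene_row[1:]
    positions = [int(p) for p in pos_row[1:]]
    strains, cells = [], []
    for ln in lines[2:]:
        fields = ln.split("\t")
        strains.append(fields[0])
        row = fields[1:]
        if len(row) != len(positions):
            raise ValueError(f"strain row {fields[0]!r} has {len(row)} cells, expected {len(positions)}")
        cells.append([c if c.strip() else MISSING for c in row])
    matrix = pd.DataFrame(cells, index=strains, columns=positions)
    for parent in (high_parent, low_parent):
        if parent not in matrix.index:
            raise ValueError(f"parent {parent!r} missing from panel")
    return StrainPanel(
        matrix=matrix,
        genes=dict(zip(positions, genes)),
        chrom=chrom,
        high_parent=high_parent,
        low_parent=low_parent,
    )
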