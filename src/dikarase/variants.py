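"""Inter-allele variant calling between phased haploid gene copies.

Variants are called by optimal global nucleotide alignment of the two
allelic sequences followed by a column walk: mismatch columns become SNPs
and runs of gap columns are merged into single insertion/deletion events.
Indels are left-aligned (VCF convention) so that representations are
unique within homopolymer runs.  Positions are reported on haplotype-1
coordinates.

Multi-base substitutions are counted as per-column SNPs, one per changed
base, rather than as a single multi-nucleotide event.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .models import (
    EXON,
    GENIC_LABELS,
    INTRON,
    PROMOTER,
    UTR3,
    UTR5,
    GeneModel,
    Variant,
    apply_variants,
    position_map,
)

__all__ = [
    "NT_SCORING",
    "partition_regions",
    "call_variants",
    "left_normalize",
    "normalize_variants",
    "annotate_coding_effects",
    "summarize_rates",
    "apply_variants",
    "position_map",
]

#: Default nucleotide scoring: match +2, mismatch -3, gap open 5, extend 2.
NT_SCORING = {"match": 2.0, "mismatch": -3.0, "gap_open": 5.0, "gap_extend": 2.0}


def _nt_aligner(scoring: dict | None = None) -> Align.PairwiseAligner:
    s = dict(NT_SCORING, **(scoring or {}))
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = s["match"]
    aligner.mismatch_score = s["mismatch"]
    aligner.open_gap_score = -s["gap_open"]
    aligner.extend_gap_score = -s["gap_extend"]
    return aligner


# --------------------------------------------------------------------- #
# Region partitioning


def partition_regions(model: GeneModel) -> list[tuple[int, int, str]]:
    """Assign every genic (and upstream promoter) base exactly one label.

    Returns sorted ``(start, end, label)`` intervals.  The transcribed
    labels take precedence over the promoter, whose annotated interval
    runs up to the start codon and therefore overlaps the 5'UTR; only the
    non-transcribed upstream part keeps the ``promoter`` label.

    Raises
    ------
    ValueError
        If the gene's annotation intervals overlap one another.
    """
    labeled: list[tuple[int, int, str]] = []
    if model.utr5[1] > model.utr5[0]:
        labeled.append((*model.utr5, UTR5))
    if model.utr3[1] > model.utr3[0]:
        labeled.append((*model.utr3, UTR3))
    labeled += [(a, b, EXON) for a, b in model.exons]
    labeled += [(a, b, INTRON) for a, b in model.introns]
    labeled.sort()
    for (a1, b1, l1), (a2, b2, l2) in zip(labeled, labeled[1:]):
        if b1 > a2:
            raise ValueError(
                f"gene {model.gene_id}: overlapping annotation "
                f"({a1},{b1},{l1}) vs ({a2},{b2},{l2})"
            )
    if model.promoter is not None:
        p0, p1 = model.promoter
        span0, span1 = model.span
        if model.strand == "+":
            pe = min(p1, span0)
            if pe > p0:
                labeled.insert(0, (p0, pe, PROMOTER))
        else:
            ps = max(p0, span1)
            if p1 > ps:
                labeled.append((ps, p1, PROMOTER))
    return labeled


def region_of(regions: list[tuple[int, int, str]], pos: int) -> str:
    for a, b, label in regions:
        if a <= pos < b:
            return label
    return ""


# --------------------------------------------------------------------- #
# Normalization


def left_normalize(v: Variant, seq: str) -> Variant:
    """Shift an indel to its leftmost equivalent position (VCF convention).

    ``seq`` is the haplotype-1 sequence the variant is expressed against.
    SNPs are returned unchanged.
    """
    if v.vtype == "SNP":
        return v
    pos = v.pos
    if v.vtype == "deletion":
        ref = v.ref
        n = len(ref)
        while pos > 0 and seq[pos - 1] == seq[pos + n - 1]:
            pos -= 1
            ref = seq[pos : pos + n]
        return replace(v, pos=pos, ref=ref)
    alt = v.alt
    while pos > 0 and alt[-1] == seq[pos - 1]:
        alt = seq[pos - 1] + alt[:-1]
        pos -= 1
    return replace(v, pos=pos, alt=alt)


def normalize_variants(variants, seq: str) -> list[Variant]:
    return sorted(
        (left_normalize(v, seq) for v in variants), key=lambda v: (v.pos, v.vtype)
    )


# --------------------------------------------------------------------- #
# Calling


def call_variants(
    seq_h1: str,
    seq_h2: str,
    model: GeneModel | None = None,
    *,
    offset: int = 0,
    gene_id: str = "",
    scoring: dict | None = None,
) -> list[Variant]:
    """Call SNPs and indels between two allelic sequences.

    Parameters
    ----------
    seq_h1, seq_h2 : str
        The two allelic sequences (haplotype 1 is the coordinate reference).
    model : GeneModel, optional
        When given, each variant is labeled with the gene region at its
        position; ``offset`` then says where ``seq_h1`` starts on the
        model's contig.
    offset : int
        Contig coordinate of ``seq_h1[0]``; reported positions are
        contig coordinates when a model is supplied, else local.

    The returned indels are left-normalized; the round-trip invariant
    ``apply_variants(seq_h1, calls) == seq_h2`` holds for every call set.
    """
    if not seq_h1 or not seq_h2:
        raise ValueError("sequences must be non-empty")
    if seq_h1 == seq_h2:
        return []
    aln = _nt_aligner(scoring).align(seq_h1, seq_h2)[0]
    g1, g2 = str(aln[0]), str(aln[1])
    regions = partition_regions(model) if model is not None else None
    gid = gene_id or (model.gene_id if model is not None else "")

    raw: list[Variant] = []
    i = 0  # position in seq_h1
    col = 0
    n = len(g1)
    while col < n:
        a, b = g1[col], g2[col]
        if a != "-" and b != "-":
            if a != b:
                raw.append(Variant(pos=i, vtype="SNP", ref=a, alt=b, gene_id=gid))
            i += 1
            col += 1
        elif b == "-":  # deletion in haplotype 2
            start = i
            ref = []
            while col < n and g2[col] == "-":
                ref.append(g1[col])
                i += 1
                col += 1
            raw.append(
                Variant(pos=start, vtype="deletion", ref="".join(ref), alt="", gene_id=gid)
            )
        else:  # insertion relative to haplotype 1
            alt = []
            while col < n and g1[col] == "-":
                alt.append(g2[col])
                col += 1
            raw.append(
                Variant(pos=i, vtype="insertion", ref="", alt="".join(alt), gene_id=gid)
            )

    out = normalize_variants(raw, seq_h1)
    if offset or regions is not None:
        shifted = []
        for v in out:
            pos = v.pos + offset
            label = region_of(regions, pos) if regions is not None else v.region
            shifted.append(replace(v, pos=pos, region=label))
        out = shifted
    return out


# --------------------------------------------------------------------- #
# Coding effects


def annotate_coding_effects(
    variants,
    model: GeneModel,
    genome_h1: str,
    domain_intervals: list[tuple[int, int]] | None = None,
    table: str = "Standard",
) -> list[Variant]:
    """Mark exonic SNPs synonymous/nonsynonymous and flag domain overlap.

    ``domain_intervals`` are 0-based half-open amino-acid intervals (e.g.
    the cupredoxin-like domains of a laccase).  Variant positions are
    contig coordinates on haplotype 1.

    Raises
    ------
    ValueError
        If an exon-labeled SNP does not map inside the CDS.
    """
    codon_table = CodonTable.unambiguous_dna_by_name[table]
    cds = model.cds_seq(genome_h1)
    out = []
    for v in variants:
        if v.vtype != "SNP" or v.region != EXON:
            out.append(v)
            continue
        cpos = model.genomic_to_cds(v.pos)
        if cpos is None:
            raise ValueError(
                f"SNP at {v.pos} labeled exonic but outside the CDS of {model.gene_id}"
            )
        codon_idx = cpos // 3
        within = cpos % 3
        codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
        alt_base = v.alt if model.strand == "+" else str(Seq(v.alt).complement())
        alt_codon = codon[:within] + alt_base + codon[within + 1 :]
        aa_ref = _translate_codon(codon, codon_table)
        aa_alt = _translate_codon(alt_codon, codon_table)
        in_dom = None
        if domain_intervals is not None:
            in_dom = any(a <= codon_idx < b for a, b in domain_intervals)
        out.append(
            replace(
                v,
                codon_index=codon_idx,
                aa_ref=aa_ref,
                aa_alt=aa_alt,
                synonymous=(aa_ref == aa_alt),
                in_domain=in_dom,
            )
        )
    return out


def _translate_codon(codon: str, table) -> str:
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


# --------------------------------------------------------------------- #
# Summaries


def summarize_rates(variants, regions: list[tuple[int, int, str]]) -> pd.DataFrame:
    """Per-region variant counts and per-site SNP rates.

    Parameters
    ----------
    variants : iterable of Variant
        Region-labeled calls for one gene pair.
    regions : list of (start, end, label)
        Output of :func:`partition_regions` for the same gene.

    Returns a frame indexed by region label with columns ``sites``,
    ``snps``, ``indels`` and ``snp_rate``; the counts over all regions sum
    to the totals of the input list (unlabeled variants are ignored).
    """
    labels = [PROMOTER, *GENIC_LABELS]
    sites = {lab: 0 for lab in labels}
    for a, b, lab in regions:
        sites[lab] = sites.get(lab, 0) + (b - a)
    snps = {lab: 0 for lab in labels}
    indels = {lab: 0 for lab in labels}
    for v in variants:
        if v.region not in sites:
            continue
        if v.vtype == "SNP":
            snps[v.region] += 1
        else:
            indels[v.region] += 1
    df = pd.DataFrame(
        {
            "sites": pd.Series(sites),
            "snps": pd.Series(snps),
            "indels": pd.Series(indels),
        }
    ).loc[labels]
    sites = df["sites"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(sites > 0, df["snps"].to_numpy() / np.maximum(sites, 1), 0.0)
    df["snp_rate"] = rate
    return df


def coding_effect_summary(variants) -> dict:
    """Counts of coding SNPs, amino-acid changes, and domain hits."""
    coding = [v for v in variants if v.vtype == "SNP" and v.region == EXON]
    nonsyn = [v for v in coding if v.synonymous is False]
    return {
        "coding_snps": len(coding),
        "nonsynonymous": len(nonsyn),
        "aa_changes": [f"{v.aa_ref}{(v.codon_index or 0) + 1}{v.aa_alt}" for v in nonsyn],
        "in_domain": sum(1 for v in nonsyn if v.in_domain),
    }
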