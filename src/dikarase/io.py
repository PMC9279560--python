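"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; the GFF3 writer/reader handle the small
feature dialect this package emits (gene, mRNA, five_prime_UTR, CDS,
three_prime_UTR), converting between internal 0-based half-open and GFF3
1-based inclusive coordinates.
"""
from __future__ import annotations

from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[tuple[str, str]], path) -> None:
    """Write (read_id, sequence) pairs with a constant maximal quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# --------------------------------------------------------------------- #
# GFF3

_FEATURE_ORDER = ("five_prime_UTR", "CDS", "three_prime_UTR")


def write_gff(models: Iterable[GeneModel], path) -> None:
    """Emit gene models as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.contig, m.span[0])):
            s, e = m.span
            gid = m.gene_id
            line = "{}\tdikarase\t{}\t{}\t{}\t.\t{}\t{}\tID={};{}\n"
            fh.write(
                line.format(m.contig, "gene", s + 1, e, m.strand, ".", gid, f"Name={gid}")
            )
            fh.write(
                line.format(
                    m.contig, "mRNA", s + 1, e, m.strand, ".",
                    f"{gid}.t1", f"Parent={gid}",
                )
            )
            feats = [("five_prime_UTR", m.utr5), ("three_prime_UTR", m.utr3)]
            feats += [("CDS", iv) for iv in m.exons]
            for i, (ftype, (a, b)) in enumerate(
                sorted(feats, key=lambda t: t[1][0])
            ):
                if b <= a:
                    continue
                phase = "0" if ftype == "CDS" else "."
                fh.write(
                    line.format(
                        m.contig, ftype, a + 1, b, m.strand, phase,
                        f"{gid}.t1.f{i}", f"Parent={gid}.t1",
                    )
                )


def read_gff(path, promoter_len: int = 3000) -> list[GeneModel]:
    """Parse the GFF3 dialect written by :func:`write_gff`."""
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            contig, _src, ftype, start, end, _score, strand, _phase, attrs = (
                line.rstrip("\n").split("\t")
            )
            iv = (int(start) - 1, int(end))
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = attr["ID"]
                genes[gid] = {
                    "contig": contig,
                    "strand": strand,
                    "cds": [],
                    "utr5": (0, 0),
                    "utr3": (0, 0),
                }
                order.append(gid)
            elif ftype in _FEATURE_ORDER:
                gid = attr["Parent"].split(".t1")[0]
                if ftype == "CDS":
                    genes[gid]["cds"].append(iv)
                elif ftype == "five_prime_UTR":
                    genes[gid]["utr5"] = iv
                else:
                    genes[gid]["utr3"] = iv
    models = []
    for gid in order:
        g = genes[gid]
        exons = tuple(sorted(g["cds"]))
        introns = tuple((a[1], b[0]) for a, b in zip(exons, exons[1:]))
        if g["strand"] == "+":
            cs = exons[0][0]
            promoter = (max(0, cs - promoter_len), cs)
        else:
            ce = exons[-1][1]
            promoter = (ce, ce + promoter_len)
        models.append(
            GeneModel(
                gene_id=gid,
                contig=g["contig"],
                strand=g["strand"],
                utr5=g["utr5"],
                exons=exons,
                introns=introns,
                utr3=g["utr3"],
                promoter=promoter,
            )
        )
    return models


# --------------------------------------------------------------------- #
# VCF

VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene pair identifier">
##INFO=<ID=REGION,Number=1,Type=String,Description="Gene region of the variant">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect (synonymous/nonsynonymous/.)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(variants, contig_for_gene: Mapping[str, str], seqs: Mapping[str, str], path) -> None:
    """Write variants as minimal VCF v4.2.

    Indels are emitted with the conventional one-base left anchor, so the
    anchored POS is the 0-based variant position (1-based anchor base).
    """
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for v in sorted(variants, key=lambda v: (contig_for_gene.get(v.gene_id, ""), v.pos)):
            contig = contig_for_gene.get(v.gene_id, v.gene_id)
            seq = seqs[contig]
            if v.vtype == "SNP":
                pos1, ref, alt = v.pos + 1, v.ref, v.alt
            elif v.vtype == "deletion":
                anchor = seq[v.pos - 1] if v.pos > 0 else "N"
                pos1, ref, alt = v.pos, anchor + v.ref, anchor
            else:  # insertion
                anchor = seq[v.pos - 1] if v.pos > 0 else "N"
                pos1, ref, alt = v.pos, anchor, anchor + v.alt
            effect = (
                "."
                if v.synonymous is None
                else ("synonymous" if v.synonymous else "nonsynonymous")
            )
            info = f"GENE={v.gene_id or '.'};REGION={v.region or '.'};EFFECT={effect}"
            fh.write(f"{contig}\t{pos1}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")
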