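"""Core genomic data structures shared across the toolkit.

All coordinates are 0-based, half-open intervals on the forward strand of
the contig, regardless of gene orientation.  GFF3 emission converts to the
standard's 1-based inclusive convention.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# Region labels used throughout variant partitioning and simulation.
PROMOTER = "promoter"
UTR5 = "5'UTR"
EXON = "exon"
INTRON = "intron"
UTR3 = "3'UTR"
GENIC_LABELS = (UTR5, EXON, INTRON, UTR3)


def revcomp(seq: str) -> str:
    """Reverse-complement a DNA string (IUPAC N preserved)."""
    return seq.translate(COMPLEMENT)[::-1]


Interval = tuple[int, int]


def _check_interval(iv: Interval, name: str) -> None:
    s, e = iv
    if not (0 <= s < e):
        raise ValueError(f"{name} interval {iv!r} is empty or negative")


def _total(ivs: Sequence[Interval]) -> int:
    return sum(e - s for s, e in ivs)


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene on one haploid contig.

    ``exons`` hold the coding pieces (CDS); the UTRs are kept as separate
    intervals.  The promoter is the stretch upstream of the start codon
    (it therefore contains the 5'UTR; region partitioning gives transcribed
    bases precedence over the promoter label).

    Parameters
    ----------
    gene_id : str
        Family-level identifier shared by the two allelic copies.
    contig : str
        Contig/chromosome name.
    strand : str
        ``"+"`` or ``"-"``.
    utr5, utr3 : tuple of int
        0-based half-open genomic intervals.
    exons : tuple of intervals
        Coding intervals in genomic order; concatenated length must be a
        multiple of three.
    introns : tuple of intervals
        Gaps between consecutive exons, in genomic order.
    promoter : tuple of int or None
        Upstream-of-start-codon interval, possibly truncated at the contig
        edge.
    """

    gene_id: str
    contig: str
    strand: str
    utr5: Interval
    exons: tuple[Interval, ...]
    introns: tuple[Interval, ...] = ()
    utr3: Interval = (0, 0)
    promoter: Interval | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: at least one exon required")
        for iv in self.exons:
            _check_interval(iv, "exon")
        starts = [iv[0] for iv in self.exons]
        if starts != sorted(starts):
            raise ValueError(f"gene {self.gene_id}: exons not sorted")
        for a, b in zip(self.exons, self.exons[1:]):
            if a[1] > b[0]:
                raise ValueError(f"gene {self.gene_id}: overlapping exons {a} {b}")
        if len(self.introns) != len(self.exons) - 1:
            raise ValueError(
                f"gene {self.gene_id}: {len(self.introns)} introns do not fit "
                f"{len(self.exons)} exons"
            )
        for (a, b), intr in zip(zip(self.exons, self.exons[1:]), self.introns):
            if intr != (a[1], b[0]):
                raise ValueError(
                    f"gene {self.gene_id}: intron {intr} does not bridge exons"
                )
        if self.cds_len % 3 != 0:
            raise ValueError(
                f"gene {self.gene_id}: CDS length {self.cds_len} not divisible by 3"
            )

    # ------------------------------------------------------------------ #
    @property
    def cds_len(self) -> int:
        return _total(self.exons)

    @property
    def tx_intervals(self) -> tuple[Interval, ...]:
        """Mature-transcript intervals (UTRs + exons) in genomic order."""
        ivs = [self.utr5, *self.exons, self.utr3]
        ivs = [iv for iv in ivs if iv[1] > iv[0]]
        return tuple(sorted(ivs))

    @property
    def tx_len(self) -> int:
        return _total(self.tx_intervals)

    @property
    def span(self) -> Interval:
        """Transcribed genomic span (introns included, promoter excluded)."""
        ivs = self.tx_intervals
        return ivs[0][0], ivs[-1][1]

    @property
    def start_codon_pos(self) -> int:
        """Forward-strand coordinate of the base adjacent to the promoter.

        For ``+`` genes this is the genomic position of the 'A' of ATG;
        for ``-`` genes it is the (exclusive) end of the last exon, i.e.
        the promoter begins at this coordinate.
        """
        if self.strand == "+":
            return self.exons[0][0]
        return self.exons[-1][1]

    # ------------------------------------------------------------------ #
    def _spliced(self, genome: str, ivs: Sequence[Interval]) -> str:
        s = "".join(genome[a:b] for a, b in ivs)
        return revcomp(s) if self.strand == "-" else s

    def transcript_seq(self, genome: str) -> str:
        """Mature mRNA sequence (5'->3', UTRs included, introns spliced)."""
        return self._spliced(genome, self.tx_intervals)

    def cds_seq(self, genome: str) -> str:
        """Coding sequence 5'->3' including the stop codon."""
        return self._spliced(genome, self.exons)

    def genomic_to_transcript(self, pos: int) -> int | None:
        """Map a forward-strand genomic position to mature transcript space.

        Returns ``None`` for intronic / non-transcribed positions.
        """
        off = 0
        for a, b in self.tx_intervals:
            if a <= pos < b:
                fo = off + (pos - a)
                return fo if self.strand == "+" else self.tx_len - 1 - fo
            off += b - a
        return None

    def genomic_to_cds(self, pos: int) -> int | None:
        """Map a genomic position into CDS space (None outside the CDS)."""
        off = 0
        for a, b in self.exons:
            if a <= pos < b:
                fo = off + (pos - a)
                return fo if self.strand == "+" else self.cds_len - 1 - fo
            off += b - a
        return None

    def shifted(self, map_pos) -> "GeneModel":
        """Return a copy with every boundary mapped through ``map_pos``.

        Used to carry a gene model from one haplotype onto the other after
        applying indels that fall strictly inside intervals.
        """

        def m(iv: Interval) -> Interval:
            return (map_pos(iv[0]), map_pos(iv[1]))

        return replace(
            self,
            utr5=m(self.utr5),
            exons=tuple(m(iv) for iv in self.exons),
            introns=tuple(m(iv) for iv in self.introns),
            utr3=m(self.utr3),
            promoter=m(self.promoter) if self.promoter else None,
        )

    def flipped(self, contig_len: int) -> "GeneModel":
        """Mirror the model onto the reverse strand of the same contig.

        Interval (s, e) becomes (L-e, L-s); the contig sequence must be
        reverse-complemented by the caller.
        """

        def f(iv: Interval) -> Interval:
            return (contig_len - iv[1], contig_len - iv[0])

        return replace(
            self,
            strand="-" if self.strand == "+" else "+",
            utr5=f(self.utr5),
            exons=tuple(f(iv) for iv in reversed(self.exons)),
            introns=tuple(f(iv) for iv in reversed(self.introns)),
            utr3=f(self.utr3),
            promoter=f(self.promoter) if self.promoter else None,
        )


@dataclass(frozen=True)
class Variant:
    """A difference between two allelic sequences, on haplotype-1 coordinates.

    ``pos`` is 0-based.  Insertions carry ``ref == ""`` (bases inserted in
    haplotype 2 before haplotype-1 position ``pos``); deletions carry
    ``alt == ""`` (haplotype-1 bases absent from haplotype 2).
    """

    pos: int
    vtype: str  # "SNP" | "insertion" | "deletion"
    ref: str
    alt: str
    gene_id: str = ""
    region: str = ""
    codon_index: int | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None
    synonymous: bool | None = None
    in_domain: bool | None = None

    def __post_init__(self) -> None:
        if self.vtype == "SNP":
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise ValueError(f"malformed SNP {self.ref}->{self.alt} @ {self.pos}")
        elif self.vtype == "insertion":
            if self.ref != "" or len(self.alt) < 1:
                raise ValueError(f"malformed insertion @ {self.pos}")
        elif self.vtype == "deletion":
            if self.alt != "" or len(self.ref) < 1:
                raise ValueError(f"malformed deletion @ {self.pos}")
        else:
            raise ValueError(f"unknown variant type {self.vtype!r}")

    @property
    def key(self) -> tuple:
        return (self.pos, self.vtype, self.ref, self.alt)


def apply_variants(seq: str, variants: Iterable[Variant]) -> str:
    """Apply a variant list to a haplotype-1 sequence, yielding haplotype 2.

    Variants must not overlap.  Reference bases are checked against ``seq``;
    a mismatch raises ``ValueError``.
    """
    out: list[str] = []
    cursor = 0
    for v in sorted(variants, key=lambda v: (v.pos, v.vtype != "insertion")):
        if v.pos < cursor:
            raise ValueError(f"overlapping variants near position {v.pos}")
        out.append(seq[cursor : v.pos])
        if v.vtype == "SNP":
            if seq[v.pos] != v.ref:
                raise ValueError(
                    f"reference mismatch at {v.pos}: expected {v.ref}, "
                    f"found {seq[v.pos]}"
                )
            out.append(v.alt)
            cursor = v.pos + 1
        elif v.vtype == "deletion":
            if seq[v.pos : v.pos + len(v.ref)] != v.ref:
                raise ValueError(f"reference mismatch for deletion at {v.pos}")
            cursor = v.pos + len(v.ref)
        else:  # insertion
            out.append(v.alt)
            cursor = v.pos
    out.append(seq[cursor:])
    return "".join(out)


def position_map(variants: Iterable[Variant]):
    """Return a function mapping haplotype-1 coordinates to haplotype-2.

    The map is exact for positions not removed by a deletion; positions
    inside a deleted block map to the block's landing point in haplotype 2.
    Interval boundaries that never fall inside an indel therefore map
    cleanly between haplotypes.
    """
    events = []  # (h1_pos, delta) applying at coordinates > h1_pos (ins) or >= end (del)
    for v in sorted(variants, key=lambda v: v.pos):
        if v.vtype == "insertion":
            events.append((v.pos, len(v.alt), 0))
        elif v.vtype == "deletion":
            events.append((v.pos, -len(v.ref), len(v.ref)))

    def map_pos(pos: int) -> int:
        delta = 0
        for p, d, span in events:
            if v_applies(pos, p, d, span):
                delta += d
            elif d < 0 and p <= pos < p + span:
                # inside the deleted block: clamp to its left edge
                delta += p - pos
        return pos + delta

    def v_applies(pos: int, p: int, d: int, span: int) -> bool:
        if d > 0:
            return pos >= p
        return pos >= p + span

    return map_pos
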